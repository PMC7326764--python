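"""Shared-miRNA competing-mRNA (ceRNA) network construction and analysis.

Two mRNAs "compete" when they share more targeting miRNAs than expected by
chance.  With m miRNAs in the map, gene A targeted by t of them, gene B by
n, and r shared, the significance is the upper-tail hypergeometric
probability

    p = 1 - sum_{i=0}^{r-1} C(t, i) C(m - t, n - i) / C(m, n)
      = P(X >= r),  X ~ Hypergeometric(m, t, n)

evaluated in log-space (log-gamma binomial coefficients) so it stays stable
for maps with hundreds of miRNAs.  Gene pairs sharing at least one miRNA
and with p below alpha become edges of the competing-mRNA network, whose
topology (degree, betweenness, closeness, power-law degree fit) and GO
over-representation are analyzed downstream.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)


class CernaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# target map


@dataclass
class TargetMap:
    """Bipartite miRNA -> gene map (deduplicated pairs, optional energies)."""

    pairs: pd.DataFrame  # columns: miRNA, gene, optionally energy

    def __post_init__(self) -> None:
        need = {"miRNA", "gene"}
        if not need <= set(self.pairs.columns):
            raise CernaError(f"target map needs columns {need}")
        self.pairs = self.pairs.drop_duplicates(subset=["miRNA", "gene"]).reset_index(drop=True)
        self._gene_mirnas: dict[str, frozenset] = {
            g: frozenset(sub["miRNA"]) for g, sub in self.pairs.groupby("gene")
        }

    @property
    def m(self) -> int:
        """Number of distinct miRNAs in the (filtered) map."""
        return self.pairs["miRNA"].nunique()

    @property
    def genes(self) -> list[str]:
        return sorted(self._gene_mirnas)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.pairs["miRNA"].unique())

    def mirnas_of(self, gene: str) -> frozenset:
        try:
            return self._gene_mirnas[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in target map") from None


def load_target_map(path, energy_cutoff: float | None = -20.0) -> TargetMap:
    """Read a miRNA/gene/energy TSV, applying the binding-energy filter.

    Pairs with predicted binding free energy above the cutoff (default
    -20 kcal/mol; weaker binding) are dropped.  Files without an energy
    column keep every pair and the cutoff is logged as inapplicable.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"miRNA", "gene"} <= set(df.columns):
        raise CernaError(f"{path}: expected columns miRNA, gene[, energy]")
    n0 = len(df)
    if "energy" in df.columns and energy_cutoff is not None:
        energy = pd.to_numeric(df["energy"], errors="coerce")
        keep = energy.isna() | (energy <= energy_cutoff)
        dropped = int((~keep).sum())
        df = df[keep]
        logger.info("energy filter (<= %g kcal/mol): dropped %d of %d pairs",
                    energy_cutoff, dropped, n0)
    else:
        logger.info("no energy column; cutoff inapplicable, %d pairs kept", n0)
    if df.empty:
        raise CernaError("no target pairs survive the energy filter")
    return TargetMap(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# shared-miRNA hypergeometric test


def _log_comb(a: float, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_tail(r: int, m: int, t: int, n: int) -> float:
    """P(X >= r) for X ~ Hypergeometric(population m, successes t, draws n).

    Computed as a log-space sum of the probability masses over the upper
    tail; returns exactly 1.0 when r <= max(0, t + n - m) or r == 0.
    """
    if not (0 <= t <= m and 0 <= n <= m):
        raise CernaError(f"invalid hypergeometric parameters m={m}, t={t}, n={n}")
    lo = max(0, t + n - m)
    hi = min(t, n)
    if r > hi:
        return 0.0
    if r <= lo:
        return 1.0
    i = np.arange(r, hi + 1, dtype=float)
    log_terms = _log_comb(t, i) + _log_comb(m - t, n - i) - _log_comb(m, float(n))
    return float(min(1.0, math.exp(logsumexp(log_terms))))


@dataclass
class CompetingPair:
    gene_a: str
    gene_b: str
    shared: int     # r
    t: int
    n: int
    m: int
    p_value: float

    def __post_init__(self) -> None:
        if self.shared > min(self.t, self.n):
            raise ValueError("shared miRNAs cannot exceed either gene's target count")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def competing_pair_test(gene_a: str, gene_b: str, target_map: TargetMap) -> CompetingPair:
    """Shared-miRNA hypergeometric test for one candidate competing pair.

    Symmetric in its gene arguments.
    """
    sa = target_map.mirnas_of(gene_a)
    sb = target_map.mirnas_of(gene_b)
    m = target_map.m
    r = len(sa & sb)
    p = hypergeom_upper_tail(r, m, len(sa), len(sb))
    return CompetingPair(gene_a, gene_b, r, len(sa), len(sb), m, p)


# ---------------------------------------------------------------------------
# network construction and topology


@dataclass
class GeneNetwork:
    """Competing-mRNA network: graph plus the edge-level test table."""

    graph: nx.Graph
    edges: pd.DataFrame   # gene_a, gene_b, shared, t, n, m, p_value
    alpha: float


def build_network(target_map: TargetMap, seed_genes: list[str] | None = None,
                  alpha: float = 0.05) -> GeneNetwork:
    """Test candidate gene pairs and keep edges with p < alpha.

    Candidates are pairs sharing at least one miRNA (any pair with no shared
    miRNA has r = 0 and p = 1).  When seed genes are given, only pairs
    involving a seed gene are tested, mirroring a hub-gene-centric network.
    """
    genes = target_map.genes
    if seed_genes is not None:
        missing = [s for s in seed_genes if s not in target_map._gene_mirnas]
        if missing:
            raise CernaError(f"seed genes absent from the target map: {missing}")
    # invert: miRNA -> genes, to enumerate sharing pairs without all-pairs scan
    by_mirna: dict[str, list[str]] = {}
    for g in genes:
        for mi in target_map.mirnas_of(g):
            by_mirna.setdefault(mi, []).append(g)
    seeds = set(seed_genes) if seed_genes is not None else None
    candidates: set[tuple[str, str]] = set()
    for members in by_mirna.values():
        members = sorted(members)
        for a, b in itertools.combinations(members, 2):
            if seeds is None or a in seeds or b in seeds:
                candidates.add((a, b))
    rows = []
    graph = nx.Graph()
    graph.add_nodes_from(seeds or [])
    for a, b in sorted(candidates):
        cp = competing_pair_test(a, b, target_map)
        rows.append({"gene_a": a, "gene_b": b, "shared": cp.shared, "t": cp.t,
                     "n": cp.n, "m": cp.m, "p_value": cp.p_value})
        if cp.p_value < alpha:
            graph.add_edge(a, b, p_value=cp.p_value, shared=cp.shared)
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "shared", "t", "n", "m", "p_value"])
    logger.info("competing network: %d candidate pairs, %d edges, %d nodes at alpha=%g",
                len(edges), graph.number_of_edges(), graph.number_of_nodes(), alpha)
    return GeneNetwork(graph, edges, alpha)


def centralities(net: GeneNetwork, top_k: int = 5) -> tuple[pd.DataFrame, set[str]]:
    """Degree, normalized betweenness and closeness per node, with ranks.

    Betweenness uses the standard (N-1)(N-2)/2 normalization for undirected
    graphs; closeness is computed within connected components with the
    Wasserman-Faust reachability scaling.  Returns the table and the
    intersection of the three top-k rank lists.
    """
    graph = net.graph if isinstance(net, GeneNetwork) else net
    if graph.number_of_nodes() == 0:
        raise CernaError("empty network")
    deg = dict(graph.degree())
    btw = nx.betweenness_centrality(graph, normalized=True)
    clo = nx.closeness_centrality(graph, wf_improved=True)
    df = pd.DataFrame({
        "gene": list(graph.nodes()),
        "degree": [deg[v] for v in graph.nodes()],
        "betweenness": [btw[v] for v in graph.nodes()],
        "closeness": [clo[v] for v in graph.nodes()],
    })
    for col in ("degree", "betweenness", "closeness"):
        df[f"{col}_rank"] = df[col].rank(ascending=False, method="min").astype(int)
    df = df.sort_values("degree_rank").reset_index(drop=True)
    tops = [set(df.nsmallest(top_k, f"{c}_rank", keep="all")["gene"].head(top_k))
            for c in ("degree", "betweenness", "closeness")]
    intersection = tops[0] & tops[1] & tops[2]
    return df, intersection


def fit_degree_powerlaw(degrees) -> tuple[float, float]:
    """Least-squares log10(frequency) ~ log10(degree) line on a degree sequence.

    Returns (slope, R^2); requires at least three distinct positive degrees.
    """
    degrees = np.asarray([d for d in degrees if d > 0])
    if degrees.size == 0:
        raise CernaError("no positive-degree nodes")
    vals, counts = np.unique(degrees, return_counts=True)
    if len(vals) < 3:
        raise CernaError("need >= 3 distinct positive degrees for a power-law fit")
    res = stats.linregress(np.log10(vals), np.log10(counts))
    return float(res.slope), float(res.rvalue ** 2)


def powerlaw_fit(net: GeneNetwork) -> tuple[float, float]:
    """Power-law check of a network's degree distribution.

    A scale-free network shows a negative slope with high R^2 in log-log
    space; a random (Erdos-Renyi-like) network does not.
    """
    graph = net.graph if isinstance(net, GeneNetwork) else net
    return fit_degree_powerlaw([d for _, d in graph.degree()])


# ---------------------------------------------------------------------------
# over-representation analysis


@dataclass
class EnrichmentRow:
    term: str
    name: str
    k: int   # hits in query
    K: int   # term size in universe
    n: int   # query size
    N: int   # universe size
    p_value: float
    significant: bool


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT gene-set file: term -> (description, genes)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def ora(query_genes: list[str], gene_sets: dict, universe: list[str],
        alpha: float = 0.05, bh: bool = False) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against gene sets.

    Gene sets are intersected with the universe; the query must be a subset
    of the universe.  Rows are sorted by p-value; p < alpha flags
    significance (raw p by default, BH column optional).
    """
    uni = set(universe)
    query = set(query_genes)
    if not query:
        raise CernaError("empty query gene list")
    if not query <= uni:
        raise CernaError(f"query genes outside the universe: {sorted(query - uni)[:5]}")
    N, n = len(uni), len(query)
    rows = []
    for term, val in gene_sets.items():
        name, members = val if isinstance(val, tuple) else ("", val)
        term_genes = set(members) & uni
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        p = hypergeom_upper_tail(k, N, K, n) if k > 0 else 1.0
        rows.append({"term": term, "name": name, "k": k, "K": K, "n": n, "N": N,
                     "p_value": p})
    df = pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    df["significant"] = df["p_value"] < alpha
    if bh and len(df):
        from statsmodels.stats.multitest import multipletests
        df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
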
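"""Dysregulation scoring of candidate feed-forward loops.

Each loop is scored by combining node-level differential expression with
edge-level differential co-expression between case and control samples:

* node magnitude  Diff = (-log10 p) * |log2 FC|, mapped through the
  two-sided-to-z transform  S = Phi^-1(2*Phi(Diff) - 1);
* edge statistic  X = [F(r_case)(-log10 p_case) - F(r_ctrl)(-log10 p_ctrl)]
  / sqrt(1.06/(n_case-3) + 1.06/(n_ctrl-3)), with F the Fisher z-transform
  (1.06/(n-3) is the classical large-sample variance of Fisher-z applied to
  a Spearman correlation); the edge score is S = Phi^-1(2*Phi(|X|) - 1);
* loop score  S_FFL = alpha * mean(node scores) + (1-alpha) * mean(edge
  scores), alpha = 0.5 by default.

Significance is an empirical p-value: the loop's score is compared against
scores of randomly assembled loops with the same edge topology, whose
miRNA, TF and gene are resampled uniformly.  ``FFLScorer`` caches node
scores per feature and edge scores per unordered feature pair so that
10 000 permutations per loop stay tractable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

from .catalog import FFL
from .expression import (
    CorrResult,
    DiffExpResult,
    ExpressionStudy,
    differential_expression,
)

log = logging.getLogger(__name__)

#: Clamp for the two-sided-to-z transform; beyond |z| = 8 the double-precision
#: normal CDF saturates, so larger values carry no ranking information.
Z_MAX = 8.0

#: Floor applied to p-values before -log10 so Diff and X stay finite.
P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Scalar building blocks
# ---------------------------------------------------------------------------

def diff_node(p: float, log2fc: float, p_floor: float = P_FLOOR) -> float:
    """Node differential-expression magnitude (-log10 p) * |log2 FC|.

    ``p`` must lie in [0, 1]; values below ``p_floor`` (including 0) are
    floored so the product stays finite.
    """
    if p < 0.0 or p > 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    return float(-math.log10(max(p, p_floor)) * abs(log2fc))


def two_sided_to_z(d: float | np.ndarray, z_max: float = Z_MAX):
    """Map a non-negative magnitude d to Phi^-1(2*Phi(d) - 1), clamped.

    This folds a two-sided normal tail into a one-sided z-score; it is
    strictly increasing until it saturates at +/- z_max (d = 0 maps to
    Phi^-1(0) = -inf, clamped to -z_max).
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("magnitude must be non-negative")
    # 2*Phi(d) - 1 = 1 - erfc(d/sqrt(2)); evaluate via the tail for accuracy
    with np.errstate(divide="ignore", over="ignore"):
        z = -special.ndtri(special.erfc(arr / math.sqrt(2.0)))
    z = np.clip(np.nan_to_num(z, nan=z_max, posinf=z_max, neginf=-z_max), -z_max, z_max)
    return float(z) if np.isscalar(d) or arr.ndim == 0 else z


def fisher_z(r: float | np.ndarray, eps: float = 1e-15):
    """Fisher transformation F(r) = 0.5 * ln((1+r)/(1-r)); |r|=1 is clamped."""
    arr = np.clip(np.asarray(r, dtype=float), -1.0 + eps, 1.0 - eps)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def edge_statistic(
    case: CorrResult, control: CorrResult, p_floor: float = P_FLOOR
) -> float:
    """Differential co-expression statistic X for one edge.

    Antisymmetric under swapping case and control; both groups need at
    least 4 samples because the variance term divides by n - 3.
    """
    for cr, name in ((case, "case"), (control, "control")):
        if cr.n < 4:
            raise ValueError(f"{name} group has n={cr.n}; need >= 4")
    num = fisher_z(case.r) * (-math.log10(max(case.p, p_floor))) - fisher_z(
        control.r
    ) * (-math.log10(max(control.p, p_floor)))
    den = math.sqrt(1.06 / (case.n - 3) + 1.06 / (control.n - 3))
    return float(num / den)


# ---------------------------------------------------------------------------
# Score records
# ---------------------------------------------------------------------------

@dataclass
class NodeScore:
    feature: str
    diff: float
    score: float


@dataclass
class EdgeScore:
    edge: tuple[str, str, str]  # (regulator, target, edge_type)
    case_corr: CorrResult
    control_corr: CorrResult
    x: float
    score: float


@dataclass
class FFLScoreRecord:
    """A scored candidate loop with its empirical significance."""

    ffl: FFL
    node_scores: list[NodeScore]
    edge_scores: list[EdgeScore]
    alpha: float
    score: float
    n_random: int = 0
    pvalue: float = math.nan
    pvalue_corrected: float = math.nan
    seed: int | None = None


def score_ffl(
    ffl: FFL,
    node_scores: Mapping[str, float],
    edge_scores: Mapping[tuple[str, str, str], float],
    alpha: float = 0.5,
) -> float:
    """Combine node and edge scores: alpha*mean(nodes) + (1-alpha)*mean(edges).

    The edge mean runs over the loop's typed edges (3 for single-regulator
    loops, 4 for composite loops, where the mutual miRNA<->TF links count
    separately).  A missing score is a hard error naming the node or edge.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    nodes = (ffl.mirna, ffl.tf, ffl.gene)
    try:
        node_mean = sum(node_scores[n] for n in nodes) / 3.0
    except KeyError as exc:
        raise KeyError(f"missing node score for {exc.args[0]!r}") from None
    edges = sorted(ffl.edges)
    try:
        edge_mean = sum(edge_scores[e] for e in edges) / len(edges)
    except KeyError as exc:
        raise KeyError(f"missing edge score for {exc.args[0]!r}") from None
    return float(alpha * node_mean + (1.0 - alpha) * edge_mean)


# ---------------------------------------------------------------------------
# Cached scorer + permutation engine
# ---------------------------------------------------------------------------

def _standardized_ranks(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise midranks, centred and L2-normalised; flags constant rows."""
    ranks = stats.rankdata(mat, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    constant = norm == 0
    norm[constant] = 1.0
    return ranks / norm[:, None], constant


def _corr_pvals(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t-approximation p-values for Spearman correlations."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return p


class FFLScorer:
    """Scores loops over one study with node/edge caching.

    Node scores are computed once per feature from a single differential
    expression pass; edge scores are memoized per unordered feature pair
    (the statistic is symmetric in the pair because Spearman correlation
    is).  ``score_candidates`` additionally precomputes dense class-pair
    edge-score matrices over the permutation universe so that the empirical
    p-value of every loop is a vectorised table lookup.
    """

    def __init__(
        self,
        study: ExpressionStudy,
        alpha: float = 0.5,
        z_max: float = Z_MAX,
        p_floor: float = P_FLOOR,
        de_method: str = "moderated_t",
    ) -> None:
        if not 0.0 < alpha < 1.0 and alpha not in (0.0, 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if study.n_case < 4 or study.n_control < 4:
            raise ValueError("edge scoring needs >= 4 samples per group (n - 3 variance)")
        self.study = study
        self.alpha = float(alpha)
        self.z_max = float(z_max)
        self.p_floor = float(p_floor)
        self.de_method = de_method
        self.de_results: dict[str, DiffExpResult] = {
            r.feature: r for r in differential_expression(study, method=de_method)
        }
        self._node_score: dict[str, NodeScore] = {}
        self._edge_cache: dict[frozenset, tuple[CorrResult, CorrResult, float, float]] = {}
        # standardized rank rows per group, shared by scalar and matrix paths
        self._zc, self._flat_case = _standardized_ranks(study.group_matrix("case"))
        self._zk, self._flat_ctrl = _standardized_ranks(study.group_matrix("control"))
        self._den = math.sqrt(
            1.06 / (study.n_case - 3) + 1.06 / (study.n_control - 3)
        )

    # -- node scores ---------------------------------------------------------

    def node_score(self, feature: str) -> NodeScore:
        ns = self._node_score.get(feature)
        if ns is None:
            de = self.de_results[feature]
            d = diff_node(de.p, de.log2fc, self.p_floor)
            ns = NodeScore(feature=feature, diff=d, score=two_sided_to_z(d, self.z_max))
            self._node_score[feature] = ns
        return ns

    # -- edge scores ---------------------------------------------------------

    def _group_corr(self, ia: int, ib: int, group: str) -> CorrResult:
        if group == "case":
            z, flat, n = self._zc, self._flat_case, self.study.n_case
        else:
            z, flat, n = self._zk, self._flat_ctrl, self.study.n_control
        if flat[ia] or flat[ib]:
            return CorrResult(r=0.0, p=1.0, n=n, flagged=True)
        r = float(np.clip(z[ia] @ z[ib], -1.0, 1.0))
        if abs(r) >= 1.0:
            return CorrResult(r=r, p=0.0, n=n)
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        return CorrResult(r=r, p=float(2.0 * stats.t.sf(abs(t), n - 2)), n=n)

    def _pair_stats(self, a: str, b: str) -> tuple[CorrResult, CorrResult, float, float]:
        key = frozenset((a, b))
        hit = self._edge_cache.get(key)
        if hit is None:
            ia, ib = self.study.index_of(a), self.study.index_of(b)
            cc = self._group_corr(ia, ib, "case")
            kk = self._group_corr(ia, ib, "control")
            x = edge_statistic(cc, kk, self.p_floor)
            hit = (cc, kk, x, two_sided_to_z(abs(x), self.z_max))
            self._edge_cache[key] = hit
        return hit

    def edge_score(self, edge: tuple[str, str, str]) -> EdgeScore:
        reg, tgt, _etype = edge
        cc, kk, x, s = self._pair_stats(reg, tgt)
        return EdgeScore(edge=edge, case_corr=cc, control_corr=kk, x=x, score=s)

    # -- loop scores ---------------------------------------------------------

    def record(self, ffl: FFL) -> FFLScoreRecord:
        """Score one loop, returning the full component breakdown."""
        nodes = [self.node_score(f) for f in (ffl.mirna, ffl.tf, ffl.gene)]
        edges = [self.edge_score(e) for e in sorted(ffl.edges)]
        score = score_ffl(
            ffl,
            {n.feature: n.score for n in nodes},
            {e.edge: e.score for e in edges},
            self.alpha,
        )
        return FFLScoreRecord(
            ffl=ffl, node_scores=nodes, edge_scores=edges, alpha=self.alpha, score=score
        )

    def score(self, ffl: FFL) -> float:
        return self.record(ffl).score

    # -- permutation universe -------------------------------------------------

    def _universe(self, ffls: Sequence[FFL], universe: str) -> dict[str, list[str]]:
        if universe == "profiled":
            pools = {cls: self.study.of_class(cls) for cls in ("miRNA", "TF", "gene")}
        elif universe == "candidate":
            pools = {
                "miRNA": sorted({f.mirna for f in ffls}),
                "TF": sorted({f.tf for f in ffls}),
                "gene": sorted({f.gene for f in ffls}),
            }
        else:
            raise ValueError(f"unknown universe {universe!r}")
        for cls, pool in pools.items():
            if not pool:
                raise ValueError(f"empty {cls} universe for permutation")
        return pools

    def _edge_score_matrix(self, rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
        """Dense edge scores between two feature index sets (vectorised)."""
        rc = np.clip(self._zc[rows_a] @ self._zc[rows_b].T, -1.0, 1.0)
        rk = np.clip(self._zk[rows_a] @ self._zk[rows_b].T, -1.0, 1.0)
        pc = _corr_pvals(rc, self.study.n_case)
        pk = _corr_pvals(rk, self.study.n_control)
        num = np.arctanh(np.clip(rc, -1 + 1e-15, 1 - 1e-15)) * (
            -np.log10(np.maximum(pc, self.p_floor))
        ) - np.arctanh(np.clip(rk, -1 + 1e-15, 1 - 1e-15)) * (
            -np.log10(np.maximum(pk, self.p_floor))
        )
        x = num / self._den
        return two_sided_to_z(np.abs(x), self.z_max)

    def _permutation_tables(self, pools: dict[str, list[str]]):
        idx = {
            cls: np.array([self.study.index_of(f) for f in pool], dtype=int)
            for cls, pool in pools.items()
        }
        nodes = {
            cls: np.array([self.node_score(f).score for f in pool])
            for cls, pool in pools.items()
        }
        mats = {
            "mt": self._edge_score_matrix(idx["miRNA"], idx["TF"]),
            "mg": self._edge_score_matrix(idx["miRNA"], idx["gene"]),
            "tg": self._edge_score_matrix(idx["TF"], idx["gene"]),
        }
        return nodes, mats

    @staticmethod
    def _random_scores(nodes, mats, composite: bool, alpha: float, n_random: int, rng):
        im = rng.integers(len(nodes["miRNA"]), size=n_random)
        it = rng.integers(len(nodes["TF"]), size=n_random)
        ig = rng.integers(len(nodes["gene"]), size=n_random)
        node_mean = (nodes["miRNA"][im] + nodes["TF"][it] + nodes["gene"][ig]) / 3.0
        e_mt = mats["mt"][im, it]
        e_mg = mats["mg"][im, ig]
        e_tg = mats["tg"][it, ig]
        if composite:
            edge_mean = (2.0 * e_mt + e_mg + e_tg) / 4.0
        else:
            edge_mean = (e_mt + e_mg + e_tg) / 3.0
        return alpha * node_mean + (1.0 - alpha) * edge_mean

    def empirical_pvalue(
        self,
        template: FFL,
        n_random: int = 10000,
        seed: int | np.random.Generator = 0,
        universe: Mapping[str, list[str]] | str = "profiled",
        real_score: float | None = None,
    ) -> float:
        """Strict-exceedance empirical p against random same-topology loops.

        Random loops inherit the template's edge topology (3 vs 4 edges) and
        draw their miRNA, TF and gene uniformly (and independently each
        iteration) from the given universe.  Returns the proportion of
        random scores strictly greater than the real score, so p = 0 is
        possible; ``(count+1)/(n+1)`` is available via ``score_candidates``.
        """
        if n_random < 1:
            raise ValueError("n_random must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if isinstance(universe, str):
            pools = self._universe([template], universe)
        else:
            pools = {cls: list(v) for cls, v in universe.items()}
        nodes, mats = self._permutation_tables(pools)
        if real_score is None:
            real_score = self.score(template)
        s = self._random_scores(
            nodes, mats, template.ffl_type == "composite-FFL", self.alpha, n_random, rng
        )
        return float(np.count_nonzero(s > real_score)) / n_random

    def score_candidates(
        self,
        ffls: Sequence[FFL],
        n_random: int = 10000,
        seed: int = 0,
        universe: str = "candidate",
    ) -> list[FFLScoreRecord]:
        """Score every candidate loop and attach empirical p-values.

        The permutation universe defaults to the molecules appearing in the
        candidate loop set; ``universe="profiled"`` uses every measured
        molecule of each class instead.  Deterministic given the candidate
        list and seed.
        """
        if n_random < 1:
            raise ValueError("n_random must be >= 1")
        ordered = sorted(ffls, key=lambda f: f.key)
        pools = self._universe(ordered, universe)
        nodes, mats = self._permutation_tables(pools)
        children = np.random.SeedSequence(seed).spawn(len(ordered))
        out: list[FFLScoreRecord] = []
        for ffl, child in zip(ordered, children):
            rec = self.record(ffl)
            rng = np.random.default_rng(child)
            s = self._random_scores(
                nodes, mats, ffl.ffl_type == "composite-FFL", self.alpha, n_random, rng
            )
            exceed = int(np.count_nonzero(s > rec.score))
            rec.n_random = n_random
            rec.pvalue = exceed / n_random
            rec.pvalue_corrected = (exceed + 1) / (n_random + 1)
            rec.seed = seed
            out.append(rec)
        return out


def empirical_pvalue(
    real_score: float,
    study: ExpressionStudy,
    template: FFL,
    n_random: int = 10000,
    seed: int = 0,
    universe: str = "profiled",
    alpha: float = 0.5,
) -> float:
    """One-shot empirical p-value for a single loop (builds a fresh scorer)."""
    scorer = FFLScorer(study, alpha=alpha)
    return scorer.empirical_pvalue(
        template, n_random=n_random, seed=seed, universe=universe, real_score=real_score
    )


# ---------------------------------------------------------------------------
# Selection and enrichment
# ---------------------------------------------------------------------------

def dysregulated_ffls(
    records: Sequence[FFLScoreRecord], p_cut: float = 0.01
) -> list[FFLScoreRecord]:
    """Records with empirical p < p_cut, sorted by (p asc, score desc, key)."""
    n_rands = {r.n_random for r in records}
    if len(n_rands) > 1:
        raise ValueError(f"records mix permutation counts {sorted(n_rands)}")
    hits = [r for r in records if r.pvalue < p_cut]
    hits.sort(key=lambda r: (r.pvalue, -r.score, r.ffl.key))
    return hits


def enrichment_test(
    selected: set[str], universe: set[str], annotated: set[str]
) -> float:
    """Upper-tail hypergeometric P(X >= k) for annotation enrichment.

    ``k`` counts selected features carrying the annotation; the population
    is the universe, successes are annotated features within the universe,
    draws are the selected set.
    """
    if not selected <= universe:
        raise ValueError("selected must be a subset of the universe")
    M = len(universe)
    K = len(annotated & universe)
    N = len(selected)
    k = len(selected & annotated)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, N))
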
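"""Synthetic case/control benchmark with planted dysregulated loops.

Generates a sample-matched expression study (miRNAs, genes, TFs), an
interaction catalog, and ground truth for a configurable number of planted
dysregulated feed-forward loops.  Background features are independent
Gaussians with no group difference.  Planted loops receive a mean shift in
cases on all three nodes and group-specific pairwise co-expression via a
Gaussian copula: target Spearman correlations are converted to latent
Pearson correlations with rho = 2*sin(pi*r_s/6), a 3x3 latent correlation
matrix is built per loop and group, and correlated latent normals are
mapped (monotonically) onto the expression scale, which preserves Spearman
correlation exactly in distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import FFL, InteractionCatalog, enumerate_ffls, write_catalog
from .expression import ExpressionStudy
from .scoring import FFLScoreRecord

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study-design and effect-size knobs for the generator.

    Defaults mirror a markedly unbalanced microarray case/control design
    (106 cases vs 20 controls) with ~200 candidate loops of which 5 are
    planted with a one-unit log2 mean shift and a case-only co-expression
    of 0.7.
    """

    n_case: int = 106
    n_control: int = 20
    n_mirna: int = 80
    n_gene: int = 150
    n_tf: int = 40
    n_candidate_ffls: int = 200
    n_planted: int = 5
    de_shift: float = 1.0
    corr_case: float = 0.7
    corr_control: float = 0.0
    noise_sd: float = 1.0
    baseline: float = 8.0
    n_extra_edges: int = 50
    planted_type: str = "miRNA-FFL"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 4 or self.n_control < 4:
            raise ValueError("need >= 4 samples per group (correlation scoring)")
        if not (abs(self.corr_case) < 1 and abs(self.corr_control) < 1):
            raise ValueError("|target correlations| must be < 1")
        if self.n_planted > self.n_candidate_ffls:
            raise ValueError("n_planted exceeds n_candidate_ffls")
        if self.n_planted * 3 > self.n_mirna + self.n_gene + self.n_tf:
            raise ValueError("too many planted loops for the feature pools")
        if self.planted_type not in ("miRNA-FFL", "TF-FFL", "composite-FFL"):
            raise ValueError(f"unknown planted type {self.planted_type!r}")


@dataclass
class GroundTruth:
    """What was planted: loops, differentially expressed nodes, rewired pairs."""

    planted_ffls: list[FFL]
    planted_nodes: set[str]
    planted_edges: set[frozenset]


def _spearman_to_latent(r_s: float) -> float:
    """Latent Pearson correlation giving Spearman r_s under a Gaussian copula."""
    return 2.0 * math.sin(math.pi * r_s / 6.0)


def _loop_latent_corr(rho: float, max_adjust: float = 0.05) -> np.ndarray:
    """3x3 latent correlation matrix with equal off-diagonals, PD-repaired.

    Eigenvalues are clipped at a small positive floor and the matrix is
    rescaled to unit diagonal; if the repair moves any entry by more than
    ``max_adjust`` the requested correlation is infeasible.
    """
    sigma = np.full((3, 3), rho)
    np.fill_diagonal(sigma, 1.0)
    w, v = np.linalg.eigh(sigma)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        fixed = (v * w) @ v.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        delta = float(np.abs(fixed - sigma).max())
        log.info("repaired non-PD latent correlation (max adjustment %.4f)", delta)
        if delta > max_adjust:
            raise ValueError(
                f"correlation {rho:.3f} infeasible for a loop (adjustment {delta:.3f}); "
                "use a smaller |corr|"
            )
        sigma = fixed
    return sigma


def _draw_loop_block(rng: np.random.Generator, rho: float, n: int) -> np.ndarray:
    """(3, n) latent standard normals with the loop's correlation structure."""
    sigma = _loop_latent_corr(rho)
    chol = np.linalg.cholesky(sigma)
    return chol @ rng.standard_normal((3, n))


def simulate(config: SimulationConfig) -> tuple[ExpressionStudy, InteractionCatalog, GroundTruth]:
    """Generate (study, catalog, ground truth); deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    mirnas = [f"miR-{i+1:03d}" for i in range(config.n_mirna)]
    genes = [f"GENE{i+1:03d}" for i in range(config.n_gene)]
    tfs = [f"TF{i+1:03d}" for i in range(config.n_tf)]
    features = mirnas + genes + tfs
    classes = {f: "miRNA" for f in mirnas}
    classes.update({f: "gene" for f in genes})
    classes.update({f: "TF" for f in tfs})
    n = config.n_case + config.n_control
    samples = [f"case_{i+1:03d}" for i in range(config.n_case)] + [
        f"ctrl_{i+1:03d}" for i in range(config.n_control)
    ]
    labels = ["case"] * config.n_case + ["control"] * config.n_control

    # background: independent, no group effect
    values = config.baseline + config.noise_sd * rng.standard_normal((len(features), n))
    findex = {f: i for i, f in enumerate(features)}
    case_cols = np.arange(config.n_case)
    ctrl_cols = np.arange(config.n_case, n)

    # planted loops on disjoint molecules
    pm = list(rng.choice(config.n_mirna, size=config.n_planted, replace=False))
    pt = list(rng.choice(config.n_tf, size=config.n_planted, replace=False))
    pg = list(rng.choice(config.n_gene, size=config.n_planted, replace=False))
    planted: list[FFL] = []
    planted_edges: set[frozenset] = set()
    for im, it, ig in zip(pm, pt, pg):
        m, t, g = mirnas[im], tfs[it], genes[ig]
        planted.append(FFL(mirna=m, tf=t, gene=g, ffl_type=config.planted_type))
        planted_edges |= {frozenset((m, t)), frozenset((m, g)), frozenset((t, g))}
        rows = [findex[m], findex[t], findex[g]]
        zc = _draw_loop_block(rng, _spearman_to_latent(config.corr_case), config.n_case)
        zk = _draw_loop_block(rng, _spearman_to_latent(config.corr_control), config.n_control)
        values[np.ix_(rows, case_cols)] = (
            config.baseline + config.de_shift + config.noise_sd * zc
        )
        values[np.ix_(rows, ctrl_cols)] = config.baseline + config.noise_sd * zk
    planted_nodes = {x for f in planted for x in (f.mirna, f.tf, f.gene)}

    # catalog: planted loop edges + decoy triples + non-loop noise edges
    catalog = InteractionCatalog()
    for f in planted:
        for src, tgt, et in f.edges:
            getattr(catalog, et).add((src, tgt))

    # incremental loop accounting so decoys add exactly one candidate each
    mg_targets: dict[str, set[str]] = {}
    tg_targets: dict[str, set[str]] = {}
    pairs: set[tuple[str, str]] = set()
    for m, g in catalog.mirna_gene:
        mg_targets.setdefault(m, set()).add(g)
    for t, g in catalog.tf_gene:
        tg_targets.setdefault(t, set()).add(g)
    pairs |= set(catalog.mirna_tf)
    pairs |= {(m, t) for t, m in catalog.tf_mirna}

    def new_loop_count(m: str, t: str, g: str) -> int:
        """Candidate loops created by adding edges m->t, m->g, t->g."""
        mg_m = mg_targets.get(m, set())
        tg_t = tg_targets.get(t, set())
        common_new = (mg_m | {g}) & (tg_t | {g})
        delta = len(common_new) - (len(mg_m & tg_t) if (m, t) in pairs else 0)
        if g not in mg_m:  # new m->g edge may close loops with other TFs of m
            delta += sum(
                1
                for m2, t2 in pairs
                if m2 == m and t2 != t and g in tg_targets.get(t2, set())
            )
        if g not in tg_t:  # new t->g edge may close loops with other miRNAs of t
            delta += sum(
                1
                for m2, t2 in pairs
                if t2 == t and m2 != m and g in mg_targets.get(m2, set())
            )
        return delta

    n_loops = len(planted)
    attempts = 0
    while n_loops < config.n_candidate_ffls and attempts < 200 * config.n_candidate_ffls:
        attempts += 1
        m = mirnas[rng.integers(config.n_mirna)]
        t = tfs[rng.integers(config.n_tf)]
        g = genes[rng.integers(config.n_gene)]
        if new_loop_count(m, t, g) != 1:
            continue
        catalog.mirna_tf.add((m, t))
        catalog.mirna_gene.add((m, g))
        catalog.tf_gene.add((t, g))
        mg_targets.setdefault(m, set()).add(g)
        tg_targets.setdefault(t, set()).add(g)
        pairs.add((m, t))
        n_loops += 1
    if n_loops < config.n_candidate_ffls:  # pragma: no cover - generous attempts
        raise RuntimeError("could not assemble the requested candidate count")

    # extra miRNA->gene edges that complete no loop
    tf_by_mirna: dict[str, set[str]] = {}
    for m, t in catalog.mirna_tf:
        tf_by_mirna.setdefault(m, set()).add(t)
    tg_by_tf: dict[str, set[str]] = {}
    for t, g in catalog.tf_gene:
        tg_by_tf.setdefault(t, set()).add(g)
    added = 0
    attempts = 0
    while added < config.n_extra_edges and attempts < 50 * max(config.n_extra_edges, 1):
        attempts += 1
        m = mirnas[rng.integers(config.n_mirna)]
        g = genes[rng.integers(config.n_gene)]
        if (m, g) in catalog.mirna_gene:
            continue
        if any(g in tg_by_tf.get(t, ()) for t in tf_by_mirna.get(m, ())):
            continue  # would close a new loop
        catalog.mirna_gene.add((m, g))
        added += 1

    study = ExpressionStudy(
        features=features,
        samples=samples,
        values=values,
        labels=labels,
        feature_class=classes,
    )
    truth = GroundTruth(
        planted_ffls=sorted(planted, key=lambda f: f.key),
        planted_nodes=planted_nodes,
        planted_edges=planted_edges,
    )
    n_cand = len(enumerate_ffls(catalog))
    if n_cand != config.n_candidate_ffls:
        log.info(
            "catalog yields %d candidate loops (target %d; decoy edge sharing adds slack)",
            n_cand,
            config.n_candidate_ffls,
        )
    return study, catalog, truth


# ---------------------------------------------------------------------------
# Recovery report
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Planted-loop recovery within the top score stratum."""

    top_k: int
    recall: float | None
    precision: float | None


def planted_recovery_report(
    records: Sequence[FFLScoreRecord],
    truth: GroundTruth,
    top_fraction: float = 0.05,
) -> RecoveryReport:
    """Recall/precision of planted loops among the top fraction by score."""
    ranked = sorted(records, key=lambda r: (-r.score, r.pvalue, r.ffl.key))
    k = math.ceil(top_fraction * len(ranked))
    top_keys = {r.ffl.key for r in ranked[:k]}
    planted_keys = {f.key for f in truth.planted_ffls}
    if not planted_keys:
        return RecoveryReport(top_k=k, recall=None, precision=None)
    hit = len(top_keys & planted_keys)
    return RecoveryReport(
        top_k=k,
        recall=hit / len(planted_keys),
        precision=hit / k if k else None,
    )


# ---------------------------------------------------------------------------
# Writers (the exact TSV dialects the loaders consume)
# ---------------------------------------------------------------------------

def write_study(study: ExpressionStudy, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = out / "expression.tsv"
    labels = out / "labels.tsv"
    classes = out / "classes.tsv"
    df = pd.DataFrame(study.values, index=study.features, columns=study.samples)
    df.index.name = "feature_id"
    df.to_csv(expr, sep="\t")
    pd.DataFrame({"sample_id": study.samples, "group": study.labels}).to_csv(
        labels, sep="\t", index=False
    )
    pd.DataFrame(
        {"feature_id": study.features, "class": [study.feature_class[f] for f in study.features]}
    ).to_csv(classes, sep="\t", index=False)
    return {"expression": expr, "labels": labels, "classes": classes}


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    pd.DataFrame(
        [(f.mirna, f.tf, f.gene, f.ffl_type) for f in truth.planted_ffls],
        columns=["mirna", "tf", "gene", "ffl_type"],
    ).to_csv(path, sep="\t", index=False)


def write_simulation(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[ExpressionStudy, InteractionCatalog, GroundTruth]:
    study, catalog, truth = simulate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_study(study, out)
    write_catalog(catalog, out / "catalog.tsv")
    write_truth(truth, out / "ground_truth.tsv")
    return study, catalog, truth
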
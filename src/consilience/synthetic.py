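"""Seeded synthetic-data generators mirroring each pipeline stage's inputs.

Every generator is fully determined by the configuration (including the
seed) and reproduces the statistical structure the corresponding stage
assumes, so the whole pipeline runs and is testable with no external tools
or downloads:

* ``gen_mti_scores`` — per-program prediction tables over planted true and
  false interactions; each program passes a true pair with its sensitivity
  and a false pair with 1 − specificity, with cross-program dependence from
  a shared Gaussian latent (correlation rho).
* ``gen_docking_scores`` — actives/decoys conformer score tables from a
  shifted bi-normal model: actives' scores are shifted by Delta (< 0 is
  better under the docking-energy convention), and a per-compound latent
  with loading lambda induces a between-conformer correlation of lambda².
  With unit variances the single-conformer expected AUC is Phi(|Delta|/√2).
* ``gen_expression`` — a two-class log2 expression matrix with a planted
  effect in the first ``n_de`` genes of class 2.
* ``gen_annotations`` — an annotation universe with one term whose genes are
  over-represented in the study set by a configurable sampling factor.

Default scales mirror the study shape the pipeline targets: a 39-active /
1448-decoy benchmark over a 26-member conformer ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .expression import ExpressionMatrix
from .metrics import TruthSet
from .mti import PredictionRecord
from .screen import ConformerScoreTable

__all__ = [
    "MtiConfig",
    "DockConfig",
    "ExprConfig",
    "AnnotConfig",
    "SyntheticConfig",
    "gen_mti_scores",
    "gen_docking_scores",
    "gen_expression",
    "gen_annotations",
]


def _check_prob(name: str, value: float, closed_top: bool = True):
    hi_ok = value <= 1.0 if closed_top else value < 1.0
    if not (0.0 <= value and hi_ok):
        raise ValueError(f"{name} must be a probability, got {value}")


@dataclass(frozen=True)
class MtiConfig:
    """Planted-truth prediction tables for three programs.

    sensitivities/specificities are per program in the order
    (microt, miranda, targetscan); rho is the latent correlation between
    programs' pass decisions.
    """

    n_true: int = 2000
    n_false: int = 2000
    sensitivities: tuple = (0.8, 0.8, 0.8)
    specificities: tuple = (0.9, 0.9, 0.9)
    rho: float = 0.0

    def __post_init__(self):
        if len(self.sensitivities) != 3 or len(self.specificities) != 3:
            raise ValueError("exactly three programs are modelled")
        for s in self.sensitivities:
            _check_prob("sensitivity", s)
        for s in self.specificities:
            _check_prob("specificity", s)
        _check_prob("rho", self.rho, closed_top=False)
        if self.n_true < 1 or self.n_false < 1:
            raise ValueError("need at least one true and one false pair")


@dataclass(frozen=True)
class DockConfig:
    """Shifted bi-normal actives/decoys docking scores over a conformer ensemble.

    ``active_shift`` (Delta) is the mean secondary-score shift of actives in
    score units (<= 0: actives score better); ``conformer_loading``
    (lambda) sets the between-conformer correlation lambda²;
    ``failure_rate`` (phi) is the per-cell probability of a failed docking;
    ``primary_noise_sd`` is the extra noise making the primary (grid) score
    a weaker ranker than the secondary (re-rank) score.
    """

    n_actives: int = 39
    n_decoys: int = 1448
    n_conformers: int = 26
    active_shift: float = -1.0
    conformer_loading: float = 0.5
    failure_rate: float = 0.0
    primary_noise_sd: float = 1.0

    def __post_init__(self):
        if self.active_shift > 0:
            raise ValueError("active_shift must be <= 0 (lower score = better)")
        _check_prob("conformer_loading", self.conformer_loading, closed_top=False)
        _check_prob("failure_rate", self.failure_rate, closed_top=False)
        if min(self.n_actives, self.n_decoys, self.n_conformers) < 1:
            raise ValueError("class and ensemble sizes must be >= 1")


@dataclass(frozen=True)
class ExprConfig:
    """Two-class log2 expression matrix with planted differential genes."""

    n_genes: int = 500
    n_de: int = 20
    n_per_class: tuple = (4, 4)
    log2_effect: float = 2.0
    noise_sd: float = 0.25
    baseline: float = 8.0

    def __post_init__(self):
        if self.n_de > self.n_genes:
            raise ValueError("cannot plant more DE genes than genes")
        if min(self.n_per_class) < 2:
            raise ValueError("each class needs at least 2 samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class AnnotConfig:
    """Annotation universe with one term enriched in the study set.

    Genes are assigned uniformly to one of ``n_terms`` terms; the study set
    is drawn without replacement with sampling weight ``enrichment_factor``
    for the planted term's genes and 1 otherwise.
    """

    n_terms: int = 20
    universe_size: int = 1000
    study_size: int = 50
    enrichment_factor: float = 10.0

    def __post_init__(self):
        if self.study_size < 1:
            raise ValueError("study set must be non-empty")
        if self.study_size > self.universe_size:
            raise ValueError("study set cannot exceed the universe")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        if self.n_terms < 2:
            raise ValueError("need at least two terms")


@dataclass(frozen=True)
class SyntheticConfig:
    """Umbrella configuration: one seed plus one block per generator."""

    seed: int = 0
    mti: MtiConfig = field(default_factory=MtiConfig)
    dock: DockConfig = field(default_factory=DockConfig)
    expr: ExprConfig = field(default_factory=ExprConfig)
    annot: AnnotConfig = field(default_factory=AnnotConfig)


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    # Independent stream per generator, all derived from the single seed.
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def _piecewise_score(u, prob, pass_lo, pass_hi, fail_lo, fail_hi):
    """Map uniform u to a score passing a threshold iff u <= prob.

    Passing u in (0, prob] maps monotonically onto (pass_lo, pass_hi];
    failing u onto (fail_lo, fail_hi].  Degenerate probs handled by clipping.
    """
    prob = np.asarray(prob, dtype=float)
    u = np.asarray(u, dtype=float)
    p = np.clip(prob, 1e-12, 1 - 1e-12)
    frac_pass = u / p
    frac_fail = (u - p) / (1 - p)
    score_pass = pass_hi - (pass_hi - pass_lo) * frac_pass
    score_fail = fail_hi - (fail_hi - fail_lo) * frac_fail
    return np.where(u <= prob, score_pass, score_fail)


def gen_mti_scores(cfg: SyntheticConfig):
    """Generate per-program prediction tables plus the planted truth set.

    Returns (records, truth): ``records`` maps program name ->
    list of :class:`PredictionRecord`; every true pair passes program p's
    thresholds with probability sensitivity_p and every false pair with
    probability 1 - specificity_p, correlated across programs through a
    shared standard-normal latent with correlation rho.
    """
    mc = cfg.mti
    rng = _rng(cfg, 0)
    n = mc.n_true + mc.n_false
    is_true = np.arange(n) < mc.n_true
    genes = np.array(
        [f"TGENE{i:05d}" if t else f"FGENE{i:05d}" for i, t in enumerate(is_true)]
    )
    mirna = "hsa-mir-syn"
    pairs = [(mirna, g) for g in genes]

    z = rng.standard_normal(n)
    sqrho, sqcomp = np.sqrt(mc.rho), np.sqrt(1.0 - mc.rho)
    programs = ("microt", "miranda", "targetscan")
    records: dict = {p: [] for p in programs}
    for j, prog in enumerate(programs):
        x = sqrho * z + sqcomp * rng.standard_normal(n)
        u = norm.cdf(x)
        prob = np.where(is_true, mc.sensitivities[j], 1.0 - mc.specificities[j])
        if prog == "microt":
            # pass iff miTG score > 0.7
            score = _piecewise_score(u, prob, 0.7, 1.0, 0.0, 0.7 - 1e-9)
            for (m, g), s in zip(pairs, score):
                records[prog].append(
                    PredictionRecord(program=prog, mirna=m, target=g,
                                     mitg_score=float(s))
                )
        elif prog == "miranda":
            # pass iff mirSVR score <= -0.1
            score = -_piecewise_score(u, prob, 0.1, 1.0, 0.0, 0.1 - 1e-9)
            for (m, g), s in zip(pairs, score):
                records[prog].append(
                    PredictionRecord(program=prog, mirna=m, target=g,
                                     mirsvr_score=float(s))
                )
        else:
            # pass iff context+ score >= -1.67 (literal direction); one
            # conserved site always present so the site rule is satisfied.
            p = np.clip(prob, 1e-12, 1 - 1e-12)
            score = np.where(
                u <= prob,
                -1.67 + (3.0 + 1.67) * (1.0 - u / p),
                -1.67 - 2.0 * np.clip((u - p) / (1.0 - p), 0.0, 1.0),
            )
            for (m, g), s in zip(pairs, score):
                records[prog].append(
                    PredictionRecord(program=prog, mirna=m, target=g,
                                     contextplus_score=float(s),
                                     conserved_site_count=1)
                )
    truth = TruthSet(
        true_set=frozenset(
            (mirna, g.upper()) for g, t in zip(genes, is_true) if t
        ),
        false_set=frozenset(
            (mirna, g.upper()) for g, t in zip(genes, is_true) if not t
        ),
    )
    return records, truth


def gen_docking_scores(cfg: SyntheticConfig):
    """Generate a conformer score table plus active/decoy labels.

    secondary(compound, conformer) = mu_class + lambda·z_compound +
    sqrt(1 - lambda²)·eps, with z and eps independent standard normals and
    mu_active = Delta, mu_decoy = 0; the primary score adds independent
    noise.  Each cell fails (both scores missing) with probability phi, but
    every compound keeps at least one scored conformer.  Returns
    (table, truth) with the 0 ps snapshot as the reference conformer.
    """
    dc = cfg.dock
    rng = _rng(cfg, 1)
    n = dc.n_actives + dc.n_decoys
    compounds = np.array(
        [f"ACT{i:05d}" for i in range(dc.n_actives)]
        + [f"DEC{i:05d}" for i in range(dc.n_decoys)]
    )
    mu = np.where(np.arange(n) < dc.n_actives, dc.active_shift, 0.0)
    conformers = [f"t{200 * i:04d}ps" for i in range(dc.n_conformers)]
    lam = dc.conformer_loading
    z = rng.standard_normal(n)
    secondary = (
        mu[:, None]
        + lam * z[:, None]
        + np.sqrt(1.0 - lam**2) * rng.standard_normal((n, dc.n_conformers))
    )
    primary = secondary + dc.primary_noise_sd * rng.standard_normal(secondary.shape)
    missing = rng.random(secondary.shape) < dc.failure_rate
    # keep the invariant: every compound docked in at least one conformer
    all_missing = missing.all(axis=1)
    if all_missing.any():
        keep = rng.integers(0, dc.n_conformers, size=int(all_missing.sum()))
        missing[np.flatnonzero(all_missing), keep] = False

    rows = []
    for i, cid in enumerate(compounds):
        for j, conf in enumerate(conformers):
            if missing[i, j]:
                continue
            rows.append(
                (cid, conf, float(primary[i, j]), float(secondary[i, j]))
            )
    frame = pd.DataFrame(
        rows, columns=["compound_id", "conformer_id", "primary_score", "secondary_score"]
    )
    table = ConformerScoreTable(frame, reference=conformers[0])
    truth = TruthSet(
        true_set=frozenset(compounds[: dc.n_actives]),
        false_set=frozenset(compounds[dc.n_actives:]),
    )
    return table, truth


def gen_expression(cfg: SyntheticConfig):
    """Generate a two-class log2 expression matrix and the planted DE genes.

    The first ``n_de`` genes get ``log2_effect`` added in class 2 (the
    "treated" class); everything else is baseline plus Gaussian noise.
    Returns (ExpressionMatrix, planted gene tuple).
    """
    ec = cfg.expr
    rng = _rng(cfg, 2)
    n1, n2 = ec.n_per_class
    genes = [f"G{i:05d}" for i in range(ec.n_genes)]
    samples = [f"ctl{i+1}" for i in range(n1)] + [f"trt{i+1}" for i in range(n2)]
    values = ec.baseline + ec.noise_sd * rng.standard_normal((ec.n_genes, n1 + n2))
    values[: ec.n_de, n1:] += ec.log2_effect
    em = ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=samples),
        classes=pd.Series(["control"] * n1 + ["treated"] * n2, index=samples),
    )
    return em, tuple(genes[: ec.n_de])


def gen_annotations(cfg: SyntheticConfig):
    """Generate an annotation term map, a study set and the planted term.

    Each universe gene belongs to exactly one term drawn uniformly; the
    study set is sampled without replacement with weight
    ``enrichment_factor`` on the planted term's genes, so the planted term's
    expected fold enrichment exceeds 1 by roughly that factor (attenuated by
    finite-universe sampling).  Returns (term_map, study_set, universe,
    planted_term).
    """
    ac = cfg.annot
    rng = _rng(cfg, 3)
    universe = [f"U{i:05d}" for i in range(ac.universe_size)]
    assignment = rng.integers(0, ac.n_terms, size=ac.universe_size)
    term_map = {
        f"TERM{t:03d}": frozenset(
            g for g, a in zip(universe, assignment) if a == t
        )
        for t in range(ac.n_terms)
    }
    term_map = {t: g for t, g in term_map.items() if g}
    planted = "TERM000"
    weights = np.where(assignment == 0, ac.enrichment_factor, 1.0)
    weights = weights / weights.sum()
    study_idx = rng.choice(
        ac.universe_size, size=ac.study_size, replace=False, p=weights
    )
    study = frozenset(universe[i] for i in study_idx)
    return term_map, study, frozenset(universe), planted
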
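"""Synthetic inputs with planted structure for every pipeline stage.

Two generators:

* :func:`generate_repeat_landscape` — a toy genome: genes placed
  non-overlapping on both strands of one contig, a background of repeat
  insertions Poisson-scattered genome-wide, and four planted gene groups
  whose promoters receive extra insertions of chosen repeat classes
  (class-A-enriched, class-B-enriched, both, neither).  The group truth is
  returned so cluster-recovery can be measured.
* :func:`generate_expression_survival` — log-scale expression for a cohort,
  event times drawn from a proportional-hazards model
  ``h(t | s) = h0 * exp(sum_i coef_i * (x_is - mu_i))`` with uniform
  censoring calibrated to a target censoring fraction, plus a feature block
  containing one feature with a requested Spearman correlation to the true
  linear predictor (Gaussian copula) and otherwise independent features.

Both generators are byte-deterministic under their config seed; sub-streams
are derived from fixed-offset seed sequences so the stages do not perturb
each other.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotation_io import GeneAnnotation, RepeatFeature
from .promoter_repeatome import extract_promoter
from .survival_signature import RiskModel, SurvivalData

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatomeSimConfig",
    "SurvivalSimConfig",
    "generate_repeat_landscape",
    "generate_expression_survival",
    "coefficient_for_arm_hazard_ratio",
    "write_truth",
]

# background insertion densities (per kb, genome-wide) and lognormal length
# medians (bp).  The enriched classes are kept sparse in the background by
# design, so that planted per-group enrichment — not background scatter —
# determines a promoter's Alu/L1 content; the other classes form a denser
# neutral backdrop.  Length medians loosely follow element biology (Alu-like
# ~300 bp, L1 fragments longer).  Config values, not claims about any genome.
_DEFAULT_DENSITIES = {
    "SINE/Alu": 0.005,
    "LINE/L1": 0.0025,
    "SINE/MIR": 0.08,
    "LINE/L2": 0.05,
    "Low_complexity": 0.06,
}
_DEFAULT_LENGTH_MEDIANS = {
    "SINE/Alu": 300.0,
    "LINE/L1": 900.0,
    "SINE/MIR": 130.0,
    "LINE/L2": 250.0,
    "Low_complexity": 60.0,
}


@dataclass
class RepeatomeSimConfig:
    """Configuration for the planted promoter-repeat landscape."""

    n_genes: int = 200
    #: fractions of (classA-enriched, classB-enriched, both, neither) genes
    group_fractions: tuple[float, float, float, float] = (0.4, 0.1, 0.1, 0.4)
    enriched_classes: tuple[str, str] = ("SINE/Alu", "LINE/L1")
    background_densities: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DENSITIES))
    length_medians: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_LENGTH_MEDIANS))
    length_sigma: float = 0.3
    enrichment_boost: int = 8
    contig: str = "chrS"
    contig_length: int = 2_000_000
    gene_length: int = 1_000
    window_bp: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_fractions) - 1.0) > 1e-9:
            raise ValueError("group_fractions must sum to 1")
        if any(d < 0 for d in self.background_densities.values()):
            raise ValueError("background densities must be >= 0")
        if self.enrichment_boost < 0:
            raise ValueError("enrichment_boost must be >= 0")

    @property
    def group_names(self) -> tuple[str, str, str, str]:
        a, b = self.enriched_classes
        return (f"{a}-enriched", f"{b}-enriched", "both", "neither")


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


def _draw_lengths(rng: np.random.Generator, median: float, sigma: float, size: int) -> np.ndarray:
    lengths = np.rint(median * np.exp(sigma * rng.standard_normal(size))).astype(int)
    return np.maximum(lengths, 20)


def generate_repeat_landscape(config: RepeatomeSimConfig) -> tuple[
        list[GeneAnnotation], list[RepeatFeature], dict[str, str]]:
    """Simulate genes, repeats and the planted gene-group truth."""
    c = config
    slot = c.contig_length // c.n_genes
    if slot < c.gene_length + 2 * c.window_bp + 2:
        raise ValueError(
            f"genome too small: slot {slot} bp cannot hold a {c.gene_length} bp gene "
            f"with {c.window_bp} bp promoter margins"
        )
    rng_place = np.random.default_rng([c.seed, 0])
    rng_bg = np.random.default_rng([c.seed, 1])
    rng_boost = np.random.default_rng([c.seed, 2])

    counts = _largest_remainder_counts(c.n_genes, c.group_fractions)
    group_of = np.repeat(np.arange(4), counts)
    rng_place.shuffle(group_of)

    genes: list[GeneAnnotation] = []
    truth: dict[str, str] = {}
    names = c.group_names
    for i in range(c.n_genes):
        lo = i * slot + c.window_bp
        hi = (i + 1) * slot - c.window_bp - c.gene_length
        start = int(rng_place.integers(lo, hi + 1))
        end = start + c.gene_length
        strand = "+" if rng_place.random() < 0.5 else "-"
        gid = f"g{i:04d}"
        genes.append(GeneAnnotation(gene_id=gid, contig=c.contig, strand=strand,
                                    tss=start if strand == "+" else end - 1,
                                    start=start, end=end))
        truth[gid] = names[group_of[i]]

    repeats: list[RepeatFeature] = []
    serial = 0
    for rclass in sorted(c.background_densities):
        density = c.background_densities[rclass]
        n_bg = int(rng_bg.poisson(density * c.contig_length / 1000.0))
        starts = rng_bg.integers(0, c.contig_length, size=n_bg)
        lengths = _draw_lengths(rng_bg, c.length_medians[rclass], c.length_sigma, n_bg)
        for s, ln in zip(starts, lengths):
            serial += 1
            repeats.append(RepeatFeature(
                contig=c.contig, start=int(s), end=int(min(s + ln, c.contig_length)),
                repeat_name=f"{rclass.rsplit('/', 1)[-1]}_sim{serial}", repeat_class=rclass))

    contig_lengths = {c.contig: c.contig_length}
    cls_a, cls_b = c.enriched_classes
    boosted = {names[0]: (cls_a,), names[1]: (cls_b,), names[2]: (cls_a, cls_b),
               names[3]: ()}
    for gene in genes:
        promoter = extract_promoter(gene, c.window_bp, contig_lengths)
        for rclass in boosted[truth[gene.gene_id]]:
            starts = rng_boost.integers(promoter.start, promoter.end, size=c.enrichment_boost)
            lengths = _draw_lengths(rng_boost, c.length_medians[rclass], c.length_sigma,
                                    c.enrichment_boost)
            for s, ln in zip(starts, lengths):
                serial += 1
                repeats.append(RepeatFeature(
                    contig=c.contig, start=int(s), end=int(min(s + ln, c.contig_length)),
                    repeat_name=f"{rclass.rsplit('/', 1)[-1]}_boost{serial}", repeat_class=rclass))

    repeats.sort(key=lambda r: (r.contig, r.start, r.end, r.repeat_name))
    return genes, repeats, truth


def write_truth(truth: Mapping[str, str], path: str | Path) -> None:
    frame = pd.Series(dict(truth), name="group").rename_axis("gene_id")
    frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# expression / survival simulation
# ---------------------------------------------------------------------------

_HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)


def coefficient_for_arm_hazard_ratio(hazard_ratio: float) -> float:
    """Coefficient giving a target hazard ratio between median-split arms.

    For a gene with unit-variance Gaussian (log-scale) expression, the mean
    difference between the above-median and below-median halves is
    ``2 * sqrt(2/pi)``, so ``coef = log(hr) / (2 * sqrt(2/pi))``.
    """
    return math.log(hazard_ratio) / (2.0 * _HALF_NORMAL_MEAN)


@dataclass
class SurvivalSimConfig:
    """Configuration for the proportional-hazards cohort simulation."""

    n_samples: int = 400
    n_genes: int = 20
    #: signature coefficients by gene name; default plants a single gene whose
    #: median split carries a hazard ratio of 2
    signature_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"gene000": coefficient_for_arm_hazard_ratio(2.0)})
    baseline_hazard: float = 0.01
    censoring_fraction: float = 0.3
    expression_sigma: float = 1.0
    n_features: int = 20
    feature_rank_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring_fraction must be in [0, 1)")
        if not set(self.signature_coefficients) <= {f"gene{i:03d}" for i in range(self.n_genes)}:
            raise ValueError("signature genes must be among the simulated genes")


def generate_expression_survival(config: SurvivalSimConfig) -> tuple[
        pd.DataFrame, SurvivalData, RiskModel, pd.DataFrame]:
    """Simulate (expression genes x samples, survival, true model, features).

    Expression is log-scale Gaussian around per-gene baselines (i.e.
    log-normal intensities); event times are exponential with hazard
    ``h0 * exp(eta)`` where ``eta`` is the centered linear predictor of the
    true model; censoring times are Uniform(0, c) with ``c`` calibrated by
    root-finding so the expected censored fraction hits the target.
    """
    c = config
    rng_expr = np.random.default_rng([c.seed, 0])
    rng_surv = np.random.default_rng([c.seed, 1])
    rng_feat = np.random.default_rng([c.seed, 2])

    gene_ids = [f"gene{i:03d}" for i in range(c.n_genes)]
    sample_ids = [f"s{i:04d}" for i in range(c.n_samples)]
    baselines = rng_expr.normal(5.0, 1.0, size=c.n_genes)
    expr = baselines[:, None] + c.expression_sigma * rng_expr.standard_normal((c.n_genes, c.n_samples))
    expression = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    expression.index.name = "gene"

    coefs = pd.Series(dict(c.signature_coefficients), dtype=float)
    centered = expression.loc[coefs.index].sub(
        pd.Series(baselines, index=gene_ids).loc[coefs.index], axis=0)
    eta = (coefs @ centered).to_numpy(dtype=float)

    hazard = c.baseline_hazard * np.exp(eta)
    event_time = rng_surv.exponential(1.0 / hazard)
    if c.censoring_fraction == 0:
        time, event = event_time, np.ones(c.n_samples, dtype=int)
    else:
        def censored_fraction(cmax: float) -> float:
            return float(np.mean(np.minimum(event_time / cmax, 1.0))) - c.censoring_fraction

        lo, hi = 1e-9, float(event_time.max()) * 1e6
        try:
            cmax = brentq(censored_fraction, lo, hi)
        except ValueError:
            cmax = hi
            warnings.warn("censoring target unattainable; using minimal censoring")
        censor_time = rng_surv.uniform(0.0, cmax, size=c.n_samples)
        censor_time = np.maximum(censor_time, 1e-9)
        event = (event_time <= censor_time).astype(int)
        time = np.minimum(event_time, censor_time)
        achieved = 1.0 - event.mean()
        logger.info("simulated censoring fraction %.3f (target %.3f)", achieved, c.censoring_fraction)
    survival = SurvivalData(pd.DataFrame({"time": time, "event": event},
                                         index=pd.Index(sample_ids, name="sample")))

    # feature block: feature000 tracks the true linear predictor with the
    # requested Spearman rho via the Gaussian-copula identity
    # rho_s = (6/pi) asin(r/2)  =>  r = 2 sin(pi rho_s / 6)
    feature_ids = [f"feature{i:03d}" for i in range(c.n_features)]
    feats = rng_feat.standard_normal((c.n_features, c.n_samples))
    if c.n_features > 0 and c.feature_rank_correlation != 0:
        sd = float(eta.std())
        eta_std = (eta - eta.mean()) / (sd if sd > 0 else 1.0)
        r = 2.0 * math.sin(math.pi * c.feature_rank_correlation / 6.0)
        feats[0] = r * eta_std + math.sqrt(max(0.0, 1.0 - r * r)) * feats[0]
    features = pd.DataFrame(feats, index=feature_ids, columns=sample_ids)
    features.index.name = "feature"

    model = RiskModel(coefs)
    return expression, survival, model, features
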
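"""Poisson collision-correction mathematics for random-barcode counting.

A pool of N template molecules is stochastically labeled, each molecule
drawing one tag uniformly and independently from a space of C = 4^L
random-sequence barcodes.  Because two molecules may draw the same tag,
the number of *distinct* tags observed after deep sequencing (S)
under-counts N; the relationship is the classical occupancy / Poisson
model, the same statistics that govern partitions in digital PCR:

    E[distinct tags | N molecules] = C * (1 - (1 - 1/C)^N)  ~  C * (1 - e^(-N/C))

Inverting the Poisson form gives the collision-corrected estimator

    N_hat = -C * ln(1 - S/C)

which is exact in expectation up to a bias factor -C*ln(1-1/C) = 1 + 1/(2C) + ...

Independently of labeling, finite read depth limits how many of the H
incorporated tags are actually *seen*.  Modeling reads as uniform
with-replacement draws from the H tags, the expected probability that
read n reveals a previously unseen tag is

    P_n = r^(n-1),   r = (H-1)/H

and the expected number of distinct tags after n reads is the geometric
partial sum

    S_n = (1 - r^n) / (1 - r)  ->  H   as n -> infinity.

This module houses those four relations, their inversions, and a
bootstrap confidence interval for the molecule-count estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "BarcodeConfig",
    "TagCountSummary",
    "SaturationCurve",
    "CopyNumberEstimate",
    "TagSpaceSaturationError",
    "estimate_molecules",
    "expected_new_tag_increment",
    "expected_observed_tags",
    "required_reads",
    "expected_incorporated_tags",
    "bootstrap_ci",
]

#: Occupancy S/C above which a saturation warning is raised.  Quantification
#: degrades well before the tag space is literally exhausted; 0.8 leaves the
#: estimator's relative sensitivity d(lnN)/d(lnS) below ~5.
DEFAULT_SATURATION_THRESHOLD = 0.8


class TagSpaceSaturationError(ValueError):
    """All C tags observed: the collision-corrected estimate diverges."""


@dataclass(frozen=True)
class BarcodeConfig:
    """The random-tag space: L bases of fully degenerate sequence, C = 4^L tags.

    Parameters
    ----------
    tag_length
        Number of random bases in the barcode (8 for the standard octamer,
        giving C = 65,536; 9 gives C = 262,144).
    """

    tag_length: int

    def __post_init__(self) -> None:
        if not isinstance(self.tag_length, (int, np.integer)) or self.tag_length < 1:
            raise ValueError(f"tag_length must be an integer >= 1, got {self.tag_length!r}")

    @property
    def tag_space(self) -> int:
        """Number of distinct tags, C = 4^L."""
        return 4 ** self.tag_length


@dataclass(frozen=True)
class TagCountSummary:
    """Per-group (taxon or sample) unique-tag count from n analyzed reads."""

    group_id: str
    reads_analyzed: int
    unique_tags_observed: int
    rejected_reads: int = 0
    subsample_seed: Optional[int] = None

    def __post_init__(self) -> None:
        s, n = self.unique_tags_observed, self.reads_analyzed
        if not (0 <= s <= n):
            raise ValueError(
                f"unique_tags_observed must satisfy 0 <= S <= n; got S={s}, n={n}"
            )
        if self.rejected_reads < 0:
            raise ValueError("rejected_reads must be non-negative")


@dataclass(frozen=True)
class SaturationCurve:
    """Tag-discovery model for H incorporated tags sampled uniformly by reads.

    The common ratio r = (H-1)/H of the geometric discovery sequence is
    derived from H; H = 1 is the degenerate single-tag case with r = 0.
    """

    incorporated_tags: int

    def __post_init__(self) -> None:
        if self.incorporated_tags < 1:
            raise ValueError(f"incorporated_tags must be >= 1, got {self.incorporated_tags}")

    @property
    def ratio(self) -> float:
        """r = (H-1)/H; 0 exactly when H = 1, always in [0, 1)."""
        h = self.incorporated_tags
        return (h - 1) / h


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Collision-corrected absolute molecule count with saturation diagnostics."""

    group_id: str
    estimate: float
    unique_tags: int
    tag_space: int
    occupancy: float
    saturation_warning: bool
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def estimate_molecules(
    counts: TagCountSummary,
    barcode: BarcodeConfig,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> CopyNumberEstimate:
    """Convert an observed unique-tag count S into a molecule count.

    N_hat = -C * ln(1 - S/C), the inversion of the Poisson occupancy model.
    Collision correction never reduces the count: N_hat >= S, with equality
    only at S = 0, and N_hat/S -> 1 as occupancy S/C -> 0.

    Raises
    ------
    TagSpaceSaturationError
        If S >= C (tag space exhausted; the estimate is undefined).
    """
    s = counts.unique_tags_observed
    c = barcode.tag_space
    if not isinstance(s, (int, np.integer)):
        raise ValueError(f"unique tag count must be an integer, got {s!r}")
    if s < 0:
        raise ValueError(f"unique tag count must be >= 0, got {s}")
    if s >= c:
        raise TagSpaceSaturationError(
            f"S={s} >= C={c}: tag space saturated, molecule count cannot be estimated"
        )
    occupancy = s / c
    # -C*ln(1 - S/C) via log1p: stable both at S -> 0 and S -> C.
    estimate = -c * math.log1p(-occupancy)
    return CopyNumberEstimate(
        group_id=counts.group_id,
        estimate=estimate,
        unique_tags=s,
        tag_space=c,
        occupancy=occupancy,
        saturation_warning=occupancy > saturation_threshold,
    )


def expected_new_tag_increment(curve: SaturationCurve, read_index: int) -> float:
    """Expected probability that read number n reveals a previously unseen tag.

    P_n = r^(n-1) with r = (H-1)/H.  P_1 = 1 always (the first read is new);
    for H = 1 every later read is a repeat (0^0 taken as 1).
    """
    if read_index < 1:
        raise ValueError(f"read_index must be >= 1, got {read_index}")
    if curve.incorporated_tags == 1:
        return 1.0 if read_index == 1 else 0.0
    return curve.ratio ** (read_index - 1)


def expected_observed_tags(curve: SaturationCurve, reads: int) -> float:
    """Expected number of distinct tags after n reads: S_n = (1-r^n)/(1-r).

    The geometric partial sum of the per-read discovery increments; it is
    non-decreasing in n, bounded by H, and converges to H as n grows.
    For H = 1 the limit r -> 0 gives S_n = 1 for every n.
    """
    if reads < 1:
        raise ValueError(f"reads must be >= 1, got {reads}")
    h = curve.incorporated_tags
    if h == 1:
        return 1.0
    r = curve.ratio
    # (1-r^n)/(1-r) = H * (1 - r^n); r^n via exp(n*log1p(-1/H)) keeps
    # precision when H is large and n*log(r) is tiny.
    return h * -math.expm1(reads * math.log1p(-1.0 / h))


def required_reads(curve: SaturationCurve, recovery_fraction: float) -> int:
    """Smallest read count n with E[distinct tags] >= f * H.

    Solves S_n >= f*H, i.e. n >= ln(1-f)/ln(r); full recovery (f = 1)
    needs unbounded depth in expectation and is rejected.
    """
    f = recovery_fraction
    if not (0.0 < f < 1.0):
        raise ValueError(f"recovery_fraction must be in (0, 1), got {f}")
    h = curve.incorporated_tags
    if h == 1:
        return 1
    n = math.ceil(math.log1p(-f) / math.log1p(-1.0 / h))
    n = max(n, 1)
    # Guard against floating-point edge: enforce the defining inequalities.
    while expected_observed_tags(curve, n) < f * h:
        n += 1
    while n > 1 and expected_observed_tags(curve, n - 1) >= f * h:
        n -= 1
    return n


def expected_incorporated_tags(barcode: BarcodeConfig, templates: int) -> float:
    """Forward occupancy model: E[distinct tags] when N molecules label uniformly.

    E[H] = C * (1 - (1 - 1/C)^N).  Composing with :func:`estimate_molecules`
    recovers N up to the analytic bias factor -C*ln(1-1/C) = 1 + 1/(2C) + ...
    """
    n = templates
    if n < 0:
        raise ValueError(f"templates must be >= 0, got {n}")
    c = barcode.tag_space
    return c * -math.expm1(n * math.log1p(-1.0 / c))


def bootstrap_ci(
    observations: Sequence[str],
    barcode: BarcodeConfig,
    replicates: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> Tuple[float, float]:
    """Percentile bootstrap interval for the molecule-count estimate.

    Reads are resampled with replacement; each resample's unique-tag count
    is collision-corrected, and the (alpha/2, 1-alpha/2) percentiles of the
    resulting estimates are returned.  Deterministic given ``seed``.

    This interval is a toolkit extension: it captures read-sampling
    variability around the point estimate, not labeling variability or
    wet-lab replicate scatter.

    Raises
    ------
    TagSpaceSaturationError
        If every resample saturates the tag space.
    """
    if replicates < 100:
        raise ValueError(f"replicates must be >= 100, got {replicates}")
    if len(observations) == 0:
        raise ValueError("observations must be non-empty")
    c = barcode.tag_space
    # Map tag strings to integer codes once; resampling then stays in numpy.
    _, codes = np.unique(np.asarray(observations, dtype=object), return_inverse=True)
    n = codes.size
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(replicates):
        resample = codes[rng.integers(0, n, size=n)]
        s = int(np.unique(resample).size)
        if s >= c:
            continue
        estimates.append(-c * math.log1p(-s / c))
    if not estimates:
        raise TagSpaceSaturationError("all bootstrap resamples saturated the tag space")
    lo, hi = np.percentile(estimates, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
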
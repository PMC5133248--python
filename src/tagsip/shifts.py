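"""Per-OTU density-shift detection with a null-calibrated limit of detection.

The Tag-SIP signal is read per OTU: its fraction-wise read counts in one
gradient are normalized to that gradient's maximum ("ratio of quantities"),
the DNA band's peak is located, and the labeled-minus-control peak density
difference is the shift. A peak only counts if its band is supported by at
least ``min_support`` contiguous fractions at half-maximum; single-point
spikes are ignored and the whole distribution (read-weighted centroid) is
compared instead. The limit of detection is calibrated from a null
treatment in which no detectable labeling is expected: the cutoff is
``factor`` × the largest null shift magnitude, and shifts at or above the
cutoff are called enriched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GradientRun, TaxonomyMap

NO_SIGNAL = "no-signal"


class DegenerateNullError(ValueError):
    """All null shifts are zero: the LOD cannot be calibrated from them."""


@dataclass
class OtuDensityProfile:
    """One OTU's normalized read distribution over a gradient's fractions."""

    otu_id: str
    gradient_id: str
    densities: np.ndarray  # g ml⁻¹, sequenced fractions, descending
    reads: np.ndarray
    ratios: np.ndarray  # reads / max(reads), in [0, 1]
    no_signal: bool = False


@dataclass
class PeakCall:
    """Location of an OTU's DNA band in one gradient.

    ``method`` is "peak" when a valid (≥ min_support fractions) band peak
    exists, "centroid" when the read-weighted mean density is the fallback,
    and "none" for profiles with no reads at all.
    """

    mode_density: float | None
    support_size: int
    secondary_peaks: list[tuple[float, int]]
    valid: bool
    method: str  # "peak" | "centroid" | "none"
    centroid_density: float | None = None
    flags: tuple[str, ...] = ()


@dataclass
class ShiftResult:
    """Paired control/labeled density difference for one OTU."""

    otu_id: str
    treatment: str
    delta_density: float | None  # g ml⁻¹, labeled − control; None when no signal
    control_peak: PeakCall
    labeled_peak: PeakCall
    method: str  # comparison actually used
    enriched: bool | None = None
    negative_shift_flag: bool = False


@dataclass
class LodCalibration:
    """Detection threshold derived from a null treatment's shifts.

    cutoff = factor × max |null shift|; summary statistics use the n−1
    (sample) standard deviation of the signed null shifts.
    """

    cutoff: float
    factor: float
    null_shifts: list[float]
    n: int = field(init=False)
    mean: float = field(init=False)
    sd: float = field(init=False)
    max_abs: float = field(init=False)
    sd_distance: float = field(init=False)
    small_n: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.null_shifts, dtype=float)
        self.n = arr.size
        self.mean = float(arr.mean())
        self.sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
        self.max_abs = float(np.abs(arr).max())
        self.sd_distance = (self.cutoff - self.mean) / self.sd if self.sd else float("nan")

    def report(self) -> str:
        """Human-readable calibration summary with a shift-magnitude histogram."""
        mags = np.abs(np.asarray(self.null_shifts, dtype=float))
        edges = np.arange(0.0, self.max_abs + 0.0015, 0.001)
        hist, edges = np.histogram(mags, bins=edges)
        lines = [
            "limit-of-detection calibration (null treatment)",
            f"  n null shifts : {self.n}" + ("  [WARNING: small n]" if self.small_n else ""),
            f"  mean          : {self.mean:.4f} g/ml",
            f"  sd (n-1)      : {self.sd:.4f} g/ml",
            f"  max |shift|   : {self.max_abs:.4f} g/ml",
            f"  factor        : {self.factor:g}",
            f"  cutoff        : {self.cutoff:.4f} g/ml",
            f"  cutoff - mean : {self.sd_distance:.1f} sd",
            "  |shift| histogram (g/ml):",
        ]
        for lo, hi, c in zip(edges[:-1], edges[1:], hist):
            lines.append(f"    [{lo:.3f}, {hi:.3f}): {c}")
        return "\n".join(lines)


@dataclass(frozen=True)
class CladeSummary:
    clade: str
    rank: str
    n_otus: int
    n_enriched: int

    @property
    def percent_enriched(self) -> float:
        return 100.0 * self.n_enriched / self.n_otus if self.n_otus else 0.0


# ---------------------------------------------------------------------------


def build_profile(counts, run: GradientRun, otu_id: str) -> OtuDensityProfile:
    """Normalize one OTU's per-fraction reads to the gradient maximum."""
    seq = run.sequenced_fractions
    reads = np.asarray(counts, dtype=float)
    if reads.shape != (len(seq),):
        raise ValueError(
            f"{otu_id}/{run.gradient_id}: {reads.size} counts for {len(seq)} sequenced fractions"
        )
    densities = np.array([f.density for f in seq])
    peak = reads.max() if reads.size else 0.0
    if peak > 0:
        ratios = reads / peak
        no_signal = False
    else:
        ratios = np.zeros_like(reads)
        no_signal = True
    return OtuDensityProfile(
        otu_id=otu_id,
        gradient_id=run.gradient_id,
        densities=densities,
        reads=reads,
        ratios=ratios,
        no_signal=no_signal,
    )


def _run_around(ratios: np.ndarray, i: int, thr: float, forbidden: set[int]) -> list[int]:
    """Contiguous indices with ratio >= thr containing i, stopping at ``forbidden``."""
    lo = i
    while lo - 1 >= 0 and ratios[lo - 1] >= thr and (lo - 1) not in forbidden:
        lo -= 1
    hi = i
    while hi + 1 < ratios.size and ratios[hi + 1] >= thr and (hi + 1) not in forbidden:
        hi += 1
    return list(range(lo, hi + 1))


def _weighted_density(densities: np.ndarray, reads: np.ndarray, idx) -> float:
    w = reads[idx]
    if w.sum() == 0:
        return float(np.mean(densities[idx]))
    return float(np.average(densities[idx], weights=w))


def detect_peaks(
    profile: OtuDensityProfile,
    support_threshold: float = 0.5,
    min_support: int = 3,
    secondary_min_ratio: float = 0.25,
) -> PeakCall:
    """Locate an OTU's DNA band and any supported secondary bands.

    The primary peak is the global-maximum fraction; its support is the
    maximal contiguous run of fractions at or above ``support_threshold`` of
    the maximum that contains the mode. A peak is valid only with support of
    at least ``min_support`` fractions — single-point spikes are rejected and
    the read-weighted centroid of the whole distribution is used instead.
    Local maxima outside the primary run reaching ``secondary_min_ratio``
    with their own support (``support_threshold`` × their height, disjoint
    from the primary run) of at least ``min_support`` are reported as
    secondary peaks, sorted by density.
    """
    if profile.no_signal:
        return PeakCall(
            mode_density=None,
            support_size=0,
            secondary_peaks=[],
            valid=False,
            method="none",
            centroid_density=None,
            flags=(NO_SIGNAL,),
        )
    r = profile.ratios
    d = profile.densities
    centroid = _weighted_density(d, profile.reads, np.arange(r.size))
    tied = np.flatnonzero(r == r.max())
    mode_idx = int(tied[0])
    mode_density = _weighted_density(d, profile.reads, tied) if tied.size > 1 else float(d[mode_idx])
    primary_run = _run_around(r, mode_idx, support_threshold * r.max(), forbidden=set())
    support = len(primary_run)
    valid = support >= min_support

    # secondary bands: local maxima outside the primary run
    primary_set = set(primary_run)
    secondary: list[tuple[float, int]] = []
    claimed: set[int] = set(primary_run)
    order = np.argsort(r)[::-1]
    for i in map(int, order):
        if i in claimed or r[i] < secondary_min_ratio:
            continue
        left = r[i - 1] if i > 0 else -np.inf
        right = r[i + 1] if i + 1 < r.size else -np.inf
        if r[i] < left or r[i] < right:
            continue
        run = _run_around(r, i, support_threshold * r[i], forbidden=primary_set)
        if set(run) & primary_set:
            continue
        claimed.update(run)
        if len(run) >= min_support:
            secondary.append((float(d[i]), len(run)))
    secondary.sort(key=lambda t: t[0])

    if valid:
        return PeakCall(
            mode_density=mode_density,
            support_size=support,
            secondary_peaks=secondary,
            valid=True,
            method="peak",
            centroid_density=centroid,
        )
    return PeakCall(
        mode_density=centroid,
        support_size=support,
        secondary_peaks=secondary,
        valid=False,
        method="centroid",
        centroid_density=centroid,
        flags=("single-point-peak",) if support == 1 else ("weak-support",),
    )


def compute_shift(control: PeakCall, labeled: PeakCall) -> tuple[float | None, str]:
    """Labeled-minus-control band density (g ml⁻¹) and the method used.

    Valid peaks are compared peak-vs-peak. If either side fell back to the
    centroid, both sides are compared centroid-vs-centroid so the comparison
    stays like-for-like. Returns ``(None, "none")`` when either side has no
    reads at all.
    """
    if NO_SIGNAL in control.flags or NO_SIGNAL in labeled.flags:
        return None, "none"
    if control.valid and labeled.valid:
        return float(labeled.mode_density - control.mode_density), "peak"
    return float(labeled.centroid_density - control.centroid_density), "centroid"


def calibrate_lod(
    null_shifts,
    factor: float = 1.5,
    min_n: int = 10,
) -> LodCalibration:
    """Set the enrichment cutoff from a null treatment's shift distribution.

    The null treatment is expected to carry no detectable labeling, so its
    shifts measure pure banding variability; the cutoff is conservatively
    ``factor`` times the largest magnitude observed.
    """
    shifts = [float(s) for s in null_shifts if s is not None]
    if not shifts or all(s == 0.0 for s in shifts):
        raise DegenerateNullError(
            "degenerate null: all null shifts are zero; specify a cutoff manually"
        )
    small = len(shifts) < min_n
    if small:
        warnings.warn(
            f"only {len(shifts)} null shifts (< {min_n}); calibration flagged as small-n",
            stacklevel=2,
        )
    max_abs = max(abs(s) for s in shifts)
    return LodCalibration(cutoff=factor * max_abs, factor=factor, null_shifts=shifts, small_n=small)


def call_enrichment(shift: float, lod: LodCalibration) -> bool:
    """Enriched iff the shift reaches the cutoff (inclusive)."""
    return shift >= lod.cutoff


def summarize_clades(
    results: list[ShiftResult],
    taxonomy: TaxonomyMap,
    rank: str = "family",
) -> list[CladeSummary]:
    """Per-clade counts and percentage of enriched OTUs at ``rank``.

    OTUs missing from the taxonomy (or unresolved at ``rank``) group under
    "unclassified". An overall "(all)" row is appended.
    """
    groups: dict[str, list[ShiftResult]] = {}
    for res in results:
        groups.setdefault(taxonomy.at_rank(res.otu_id, rank), []).append(res)
    out = [
        CladeSummary(
            clade=clade,
            rank=rank,
            n_otus=len(rs),
            n_enriched=sum(1 for r in rs if r.enriched),
        )
        for clade, rs in sorted(groups.items())
    ]
    out.append(
        CladeSummary(
            clade="(all)",
            rank=rank,
            n_otus=len(results),
            n_enriched=sum(1 for r in results if r.enriched),
        )
    )
    return out
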
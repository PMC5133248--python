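"""End-to-end Tag-SIP analysis: inputs → profiles → peaks → shifts → calls.

The workflow mirrors the bench protocol: select the sequenced fraction
window from the DNA distribution, filter to abundant well-covered OTUs,
build per-OTU density profiles for each gradient of a labeled/control pair,
locate band peaks, difference them, calibrate the limit of detection from
the null-treatment pair, and call enrichment per OTU, finally summarizing
calls per clade.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as gio
from . import shifts as sh


@dataclass
class RunConfig:
    """All analysis parameters with their module defaults.

    Unknown keys are rejected so config typos fail loudly.
    """

    n_select_fractions: int = 20
    min_mean_reads: float = 400.0
    top_n: int = 100
    read_stat: str = "mean"
    read_quantifier: str = "any"
    support_threshold: float = 0.5
    min_support: int = 3
    secondary_min_ratio: float = 0.25
    use_secondary: bool = False  # compare max-over-peaks instead of primary only
    lod_factor: float = 1.5
    lod_min_n: int = 10
    manual_cutoff: float | None = None
    clade_rank: str = "family"
    seed: int | None = None  # recorded in output headers; analysis is deterministic

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise gio.ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PairAnalysis:
    treatment: str
    labeled_gradient_id: str
    control_gradient_id: str
    results: list[sh.ShiftResult]


@dataclass
class AnalysisResult:
    pairs: list[PairAnalysis]
    lod: sh.LodCalibration | None
    clade_summaries: dict[str, list[sh.CladeSummary]]  # per treatment
    config: RunConfig

    def shift_frame(self) -> pd.DataFrame:
        rows = []
        for pa in self.pairs:
            for r in pa.results:
                rows.append(
                    {
                        "otu_id": r.otu_id,
                        "treatment": r.treatment,
                        "control_density": _r4(r.control_peak.mode_density),
                        "labeled_density": _r4(r.labeled_peak.mode_density),
                        "delta_density": _r4(r.delta_density),
                        "control_support": r.control_peak.support_size,
                        "labeled_support": r.labeled_peak.support_size,
                        "n_secondary_peaks": len(r.labeled_peak.secondary_peaks),
                        "method": r.method,
                        "enriched": int(bool(r.enriched)) if r.enriched is not None else "",
                        "negative_shift": int(r.negative_shift_flag),
                        "flags": ",".join(r.control_peak.flags + r.labeled_peak.flags),
                    }
                )
        return pd.DataFrame(rows)

    def clade_frame(self) -> pd.DataFrame:
        rows = [
            {
                "treatment": treatment,
                "rank": cs.rank,
                "clade": cs.clade,
                "n_otus": cs.n_otus,
                "n_enriched": cs.n_enriched,
                "percent_enriched": round(cs.percent_enriched, 1),
            }
            for treatment, summaries in self.clade_summaries.items()
            for cs in summaries
        ]
        return pd.DataFrame(rows)


def _r4(x: float | None) -> float | str:
    return "" if x is None else round(x, 4)


def _peak_for_shift(call: sh.PeakCall, use_secondary: bool) -> sh.PeakCall:
    """Optionally re-point a call at its densest supported peak (bimodal OTUs)."""
    if not (use_secondary and call.valid and call.secondary_peaks):
        return call
    best_density, best_support = max(call.secondary_peaks, key=lambda t: t[0])
    if best_density > call.mode_density:
        return sh.PeakCall(
            mode_density=best_density,
            support_size=best_support,
            secondary_peaks=call.secondary_peaks,
            valid=True,
            method="peak",
            centroid_density=call.centroid_density,
            flags=call.flags + ("secondary-used",),
        )
    return call


def analyze_pair(
    table: gio.OtuCountTable,
    runs: dict[str, gio.GradientRun],
    entry: gio.PairEntry,
    config: RunConfig,
) -> PairAnalysis:
    """Shift every OTU of one labeled/control gradient pair."""
    run_c = runs[entry.control_gradient_id]
    run_l = runs[entry.labeled_gradient_id]
    counts_c = table.for_gradient(entry.control_gradient_id)
    counts_l = table.for_gradient(entry.labeled_gradient_id)
    results = []
    for otu in table.otu_ids:
        prof_c = sh.build_profile(counts_c.loc[otu].to_numpy(), run_c, otu)
        prof_l = sh.build_profile(counts_l.loc[otu].to_numpy(), run_l, otu)
        peak_c = sh.detect_peaks(
            prof_c, config.support_threshold, config.min_support, config.secondary_min_ratio
        )
        peak_l = sh.detect_peaks(
            prof_l, config.support_threshold, config.min_support, config.secondary_min_ratio
        )
        peak_l_used = _peak_for_shift(peak_l, config.use_secondary)
        delta, method = sh.compute_shift(peak_c, peak_l_used)
        results.append(
            sh.ShiftResult(
                otu_id=otu,
                treatment=entry.treatment_name,
                delta_density=delta,
                control_peak=peak_c,
                labeled_peak=peak_l_used,
                method=method,
                negative_shift_flag=delta is not None and delta < 0,
            )
        )
    return PairAnalysis(
        treatment=entry.treatment_name,
        labeled_gradient_id=entry.labeled_gradient_id,
        control_gradient_id=entry.control_gradient_id,
        results=results,
    )


def _ensure_selected(runs: list[gio.GradientRun], config: RunConfig) -> dict[str, gio.GradientRun]:
    """Honor pre-flagged sequenced fractions; otherwise select the DNA window."""
    out = {}
    for run in runs:
        if not any(f.sequenced for f in run.fractions):
            run = gio.select_fractions(run, n=config.n_select_fractions)
        out[run.gradient_id] = run
    return out


def analyze(
    runs: list[gio.GradientRun],
    table: gio.OtuCountTable,
    taxonomy: gio.TaxonomyMap,
    manifest: gio.PairManifest,
    config: RunConfig | None = None,
) -> AnalysisResult:
    """Full analysis of a paired experiment.

    The limit of detection comes from the manifest's null-treatment pair(s);
    with no null treatment a ``manual_cutoff`` must be supplied in the
    config. Null-pair OTUs are reported too (their calls use the same
    cutoff, and essentially none should be enriched).
    """
    config = config or RunConfig()
    if not manifest.entries:
        raise gio.ValidationError("pairing manifest lists no labeled/control pairs")
    run_map = _ensure_selected(runs, config)
    table.validate_against(run_map)
    filtered = gio.filter_otus(
        table,
        list(run_map.values()),
        min_mean_reads=config.min_mean_reads,
        top_n=config.top_n,
        pairs=manifest.entries,
        stat=config.read_stat,
        quantifier=config.read_quantifier,
    )

    pair_analyses = [analyze_pair(filtered, run_map, e, config) for e in manifest.entries]

    if config.manual_cutoff is not None:
        lod = sh.LodCalibration(
            cutoff=config.manual_cutoff, factor=float("nan"), null_shifts=[config.manual_cutoff]
        )
    else:
        null_pairs = [pa for pa in pair_analyses if pa.treatment == manifest.null_treatment_name]
        if not manifest.null_treatment_name or not null_pairs:
            raise gio.ValidationError(
                "no null treatment in the manifest and no manual_cutoff configured; "
                "either name a null treatment or set manual_cutoff"
            )
        null_shifts = [
            r.delta_density for pa in null_pairs for r in pa.results if r.delta_density is not None
        ]
        lod = sh.calibrate_lod(null_shifts, factor=config.lod_factor, min_n=config.lod_min_n)

    for pa in pair_analyses:
        for r in pa.results:
            if r.delta_density is not None:
                r.enriched = sh.call_enrichment(r.delta_density, lod)

    summaries = {
        pa.treatment: sh.summarize_clades(
            [r for r in pa.results if r.delta_density is not None], taxonomy, config.clade_rank
        )
        for pa in pair_analyses
    }
    return AnalysisResult(pairs=pair_analyses, lod=lod, clade_summaries=summaries, config=config)


def analyze_paths(
    metadata: str | Path,
    counts: str | Path,
    taxonomy: str | Path,
    manifest: str | Path,
    config: RunConfig | None = None,
) -> AnalysisResult:
    """File-based entry point used by the command line."""
    return analyze(
        runs=gio.read_fraction_metadata(metadata),
        table=gio.read_otu_table(counts),
        taxonomy=gio.read_taxonomy(taxonomy),
        manifest=gio.read_manifest(manifest),
        config=config,
    )


def _header(config: RunConfig) -> str:
    seed = "NA" if config.seed is None else config.seed
    return f"# tagsip v{__version__} | config_hash={config.config_hash()} | seed={seed}\n"


def write_results(result: AnalysisResult, outdir: str | Path) -> dict[str, Path]:
    """Write shift TSV, clade TSV, and the calibration report with headers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = _header(result.config)
    paths = {
        "shifts": outdir / "shifts.tsv",
        "clades": outdir / "clade_summary.tsv",
        "calibration": outdir / "lod_calibration.txt",
    }
    with open(paths["shifts"], "w") as fh:
        fh.write(head)
        result.shift_frame().to_csv(fh, sep="\t", index=False)
    with open(paths["clades"], "w") as fh:
        fh.write(head)
        result.clade_frame().to_csv(fh, sep="\t", index=False)
    with open(paths["calibration"], "w") as fh:
        fh.write(head)
        if result.lod is not None:
            fh.write(result.lod.report() + "\n")
            fh.write("# machine-readable\n")
            for key in ("cutoff", "factor", "n", "mean", "sd", "max_abs", "sd_distance"):
                fh.write(f"{key}={getattr(result.lod, key)}\n")
    return paths
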
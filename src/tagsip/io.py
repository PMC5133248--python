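"""Tabular input/output for gradient-fraction SIP experiments.

Four plain-text tables describe a Tag-SIP experiment:

* fraction metadata — one row per collected fraction (gradient id, fraction
  index, buoyant density in g ml⁻¹, DNA quantity, sequenced flag);
* OTU count table — reads per OTU per sequenced fraction, TSV with columns
  named ``<gradient_id>:<fraction_index>``;
* taxonomy — OTU id to semicolon-delimited lineage;
* pairing manifest — YAML mapping each labeled gradient to its unlabeled
  control and naming the null treatment used for LOD calibration.

Fraction index 1 is the first fraction collected, i.e. the densest (the
bottom of the gradient is displaced first), so density must be strictly
decreasing in fraction index; this is validated, never assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

DENSITY_RANGE = (1.60, 1.80)  # plausible CsCl window, g ml⁻¹; outside → warning

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

METADATA_COLUMNS = ["gradient_id", "fraction_index", "density_g_ml", "dna_quantity", "sequenced"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class FractionRecord:
    """One collected gradient fraction."""

    gradient_id: str
    fraction_index: int
    density: float  # g ml⁻¹
    dna_quantity: float  # ng (unit recorded in the metadata header)
    sequenced: bool = False


@dataclass
class GradientRun:
    """All fractions of one gradient, ordered by fraction index."""

    gradient_id: str
    fractions: list[FractionRecord]
    treatment: str = ""  # "control" or "labeled"
    substrate: str = ""

    def __post_init__(self) -> None:
        self.fractions = sorted(self.fractions, key=lambda f: f.fraction_index)
        self.validate()

    def validate(self) -> None:
        if len(self.fractions) < 3:
            raise ValidationError(
                f"gradient {self.gradient_id!r} has {len(self.fractions)} fractions; need >= 3"
            )
        idx = [f.fraction_index for f in self.fractions]
        if len(set(idx)) != len(idx):
            dupes = sorted({i for i in idx if idx.count(i) > 1})
            raise ValidationError(f"gradient {self.gradient_id!r}: duplicate fraction indices {dupes}")
        dens = np.array([f.density for f in self.fractions])
        bad = np.where(np.diff(dens) >= 0)[0]
        if bad.size:
            pts = ", ".join(
                f"fraction {idx[i]}->{idx[i + 1]} ({dens[i]:.4f}->{dens[i + 1]:.4f})" for i in bad
            )
            raise ValidationError(
                f"gradient {self.gradient_id!r}: density must strictly decrease with "
                f"fraction index; inversion at {pts}"
            )
        lo, hi = DENSITY_RANGE
        if dens.min() < lo or dens.max() > hi:
            warnings.warn(
                f"gradient {self.gradient_id!r}: densities outside the plausible CsCl "
                f"window [{lo}, {hi}] g/ml",
                stacklevel=3,
            )

    @property
    def sequenced_fractions(self) -> list[FractionRecord]:
        return [f for f in self.fractions if f.sequenced]

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class PairEntry:
    labeled_gradient_id: str
    control_gradient_id: str
    treatment_name: str


@dataclass
class PairManifest:
    """Labeled→control gradient pairing plus the designated null treatment."""

    entries: list[PairEntry]
    null_treatment_name: str = ""

    def __post_init__(self) -> None:
        labeled = [e.labeled_gradient_id for e in self.entries]
        if len(set(labeled)) != len(labeled):
            raise ValidationError("each labeled gradient must map to exactly one control")

    @property
    def null_entries(self) -> list[PairEntry]:
        return [e for e in self.entries if e.treatment_name == self.null_treatment_name]

    @property
    def non_null_entries(self) -> list[PairEntry]:
        return [e for e in self.entries if e.treatment_name != self.null_treatment_name]


@dataclass
class TaxonomyMap:
    """OTU id → ordered lineage (domain … genus)."""

    lineages: dict[str, tuple[str, ...]]

    def at_rank(self, otu_id: str, rank: str) -> str:
        try:
            pos = RANKS.index(rank)
        except ValueError:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None
        lin = self.lineages.get(otu_id, ())
        if pos < len(lin) and lin[pos]:
            return lin[pos]
        return "unclassified"


@dataclass
class OtuCountTable:
    """Per-fraction OTU read counts.

    Wraps a DataFrame with OTU ids as the index and a two-level column
    MultiIndex ``(gradient_id, fraction_index)``.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.columns.nlevels != 2:
            raise ValidationError("count table needs (gradient_id, fraction_index) columns")
        arr = self.counts.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValidationError("counts must be finite and non-negative")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def gradient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.counts.columns.get_level_values(0)))

    def for_gradient(self, gradient_id: str) -> pd.DataFrame:
        """Counts for one gradient, columns = fraction indices (ascending)."""
        sub = self.counts[gradient_id]
        return sub[sorted(sub.columns)]

    def validate_against(self, runs: dict[str, GradientRun]) -> None:
        """Every column must resolve to a sequenced FractionRecord."""
        for gid, fidx in self.counts.columns:
            if gid not in runs:
                raise ValidationError(f"count column references unknown gradient {gid!r}")
            seq = {f.fraction_index for f in runs[gid].sequenced_fractions}
            if fidx not in seq:
                raise ValidationError(
                    f"count column {gid}:{fidx} does not resolve to a sequenced fraction"
                )


# ---------------------------------------------------------------------------
# readers / writers


def read_fraction_metadata(path: str | Path) -> list[GradientRun]:
    """Read fraction metadata (CSV or TSV) into validated GradientRuns."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"metadata file {path} missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["gradient_id", "fraction_index"])
    if dup.any():
        rows = df.loc[dup, ["gradient_id", "fraction_index"]].itertuples(index=False)
        raise ValidationError(
            "duplicate (gradient, fraction) rows: " + ", ".join(f"{g}:{i}" for g, i in rows)
        )
    runs = []
    for gid, grp in df.groupby("gradient_id", sort=True):
        fracs = [
            FractionRecord(
                gradient_id=str(gid),
                fraction_index=int(r.fraction_index),
                density=float(r.density_g_ml),
                dna_quantity=float(r.dna_quantity),
                sequenced=bool(int(r.sequenced)),
            )
            for r in grp.itertuples(index=False)
        ]
        runs.append(GradientRun(gradient_id=str(gid), fractions=fracs))
    return runs


def write_fraction_metadata(runs: list[GradientRun], path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    rows = [
        (f.gradient_id, f.fraction_index, f"{f.density:.6f}", f"{f.dna_quantity:.6f}", int(f.sequenced))
        for run in runs
        for f in run.fractions
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep=sep, index=False)


def read_otu_table(path: str | Path) -> OtuCountTable:
    """Read a TSV count table; columns are ``<gradient_id>:<fraction_index>``."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="otu_id")
    cols = []
    for c in df.columns:
        gid, _, fidx = str(c).rpartition(":")
        if not gid:
            raise ValidationError(f"count column {c!r} is not of the form gradient_id:fraction_index")
        cols.append((gid, int(fidx)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["gradient_id", "fraction_index"])
    return OtuCountTable(df.astype(np.int64))


def write_otu_table(table: OtuCountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.columns = [f"{g}:{i}" for g, i in df.columns]
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"otu_id", "lineage"} <= set(df.columns):
        raise ValidationError(f"taxonomy file {path} must have columns otu_id, lineage")
    lineages = {
        str(r.otu_id): tuple(p.strip() for p in str(r.lineage).split(";"))
        for r in df.itertuples(index=False)
    }
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    rows = [(otu, ";".join(lin)) for otu, lin in tax.lineages.items()]
    pd.DataFrame(rows, columns=["otu_id", "lineage"]).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> PairManifest:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    entries = [
        PairEntry(
            labeled_gradient_id=str(p["labeled"]),
            control_gradient_id=str(p["control"]),
            treatment_name=str(p["treatment"]),
        )
        for p in doc.get("pairs", [])
    ]
    return PairManifest(entries=entries, null_treatment_name=str(doc.get("null_treatment", "")))


def write_manifest(manifest: PairManifest, path: str | Path) -> None:
    doc = {
        "null_treatment": manifest.null_treatment_name,
        "pairs": [
            {"labeled": e.labeled_gradient_id, "control": e.control_gradient_id, "treatment": e.treatment_name}
            for e in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# selection / filtering


def select_fractions(run: GradientRun, n: int = 20) -> GradientRun:
    """Mark for sequencing the contiguous ``n``-fraction window with most DNA.

    The DNA band sits in a contiguous density range, so the window of ``n``
    consecutive fractions maximizing summed DNA quantity is selected; ties go
    to the lowest starting index. Returns a new run with ``sequenced`` set on
    exactly the selected fractions.
    """
    if len(run.fractions) < n:
        raise ValidationError(
            f"gradient {run.gradient_id!r}: cannot select {n} of {len(run.fractions)} fractions"
        )
    dna = np.array([f.dna_quantity for f in run.fractions], dtype=float)
    window_sums = np.convolve(dna, np.ones(n), mode="valid")
    start = int(np.argmax(window_sums))  # argmax returns the first maximum → lowest start
    chosen = set(range(start, start + n))
    fracs = [replace(f, sequenced=(i in chosen)) for i, f in enumerate(run.fractions)]
    return GradientRun(
        gradient_id=run.gradient_id, fractions=fracs, treatment=run.treatment, substrate=run.substrate
    )


def filter_otus(
    table: OtuCountTable,
    runs: list[GradientRun],
    min_mean_reads: float = 400.0,
    top_n: int = 100,
    pairs: list[PairEntry] | None = None,
    stat: str = "mean",
    quantifier: str = "any",
) -> OtuCountTable:
    """Keep abundant, well-covered OTUs.

    An OTU survives when (a) it ranks in the global ``top_n`` by total reads
    (ties broken lexicographically by OTU id) and (b) its per-sequenced-
    fraction read ``stat`` ("mean" or "min") reaches ``min_mean_reads`` in at
    least one gradient (``quantifier="any"``; "all" requires both) of every
    analyzed pair. Without ``pairs``, any single gradient suffices. The
    depth rule suppresses artifacts from random banding of very rare OTUs.
    """
    if stat not in ("mean", "min"):
        raise ValueError("stat must be 'mean' or 'min'")
    if quantifier not in ("any", "all"):
        raise ValueError("quantifier must be 'any' or 'all'")
    df = table.counts
    totals = df.sum(axis=1)
    ranked = sorted(df.index, key=lambda o: (-totals[o], o))
    top = set(ranked[:top_n])

    def gradient_stat(otu: str, gid: str) -> float:
        if gid not in df.columns.get_level_values(0):
            return 0.0
        vals = df.loc[otu, gid].to_numpy(dtype=float)
        return float(vals.mean() if stat == "mean" else vals.min())

    if pairs:
        groups = [(e.labeled_gradient_id, e.control_gradient_id) for e in pairs]
    else:
        groups = [tuple(table.gradient_ids())]

    keep = []
    for otu in df.index:
        if otu not in top:
            continue
        ok = True
        for gids in groups:
            stats = [gradient_stat(otu, g) for g in gids]
            hit = (any if quantifier == "any" else all)(s >= min_mean_reads for s in stats)
            if not hit:
                ok = False
                break
        if ok:
            keep.append(otu)
    if not keep:
        warnings.warn("no OTUs survive filtering; returning an empty table", stacklevel=2)
    return OtuCountTable(df.loc[keep])
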
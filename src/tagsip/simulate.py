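"""Synthetic CsCl-gradient Tag-SIP experiments.

Simulates isopycnic banding of a mixed community, fraction collection, DNA
quantification, fraction selection, and amplicon read sampling, writing
exactly the text formats the analysis pipeline reads plus a truth table of
imposed band centers and shifts. Parameter-recovery tests compare the
pipeline's recovered shifts with that truth.

Model: each OTU (or subpopulation) bands as a Gaussian in density,
N(center, band_sd²), with center = gc_intercept + gc_slope·GC +
excess·delta_max_15N. Fractions are equal-width density bins; fraction 1 is
the densest (collected first). Reads are drawn multinomially across
(OTU, fraction) cells of the sequenced window, so per-gradient read totals
are conserved exactly. DNA quantity per fraction is the community band mass
with lognormal measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import io as gio
from .isotopes import DELTA_MAX_15N

TOTAL_DNA_NG = 750.0  # DNA loaded per gradient, split across fractions


@dataclass(frozen=True)
class SubPop:
    """A subpopulation of an OTU with its own labeling level (bimodal bands)."""

    weight: float
    atom_fraction_excess: float


@dataclass
class SimOtu:
    otu_id: str
    gc_content: float
    rel_abundance: float
    atom_fraction_excess: float = 0.0
    subpopulations: list[SubPop] | None = None
    lineage: str = "Bacteria;unclassified;unclassified;unclassified;unclassified;unclassified"

    def components(self, labeled: bool) -> list[SubPop]:
        """(weight, excess) components; controls band unlabeled."""
        if not labeled:
            return [SubPop(1.0, 0.0)]
        if self.subpopulations:
            total = sum(s.weight for s in self.subpopulations)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.otu_id}: subpopulation weights sum to {total}, not 1")
            return list(self.subpopulations)
        return [SubPop(1.0, self.atom_fraction_excess)]


@dataclass
class SimConfig:
    n_fractions: int = 50
    density_min: float = 1.66  # g ml⁻¹
    density_max: float = 1.77
    band_sd: float = 0.004  # Gaussian band width in density units
    reads_per_gradient: int = 4_000_000
    n_select_fractions: int = 20
    gc_intercept: float = 1.660  # GC→density relation, g ml⁻¹
    gc_slope: float = 0.098
    delta_max_15n: float = DELTA_MAX_15N
    dna_noise_sigma: float = 0.1  # lognormal sd of fraction DNA quantification
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_max <= self.density_min:
            raise ValueError("density_max must exceed density_min")
        if self.band_sd <= 0:
            raise ValueError("band_sd must be > 0")

    @property
    def fraction_width(self) -> float:
        return (self.density_max - self.density_min) / self.n_fractions

    def fraction_edges(self) -> np.ndarray:
        """Density bin edges, ascending."""
        return np.linspace(self.density_min, self.density_max, self.n_fractions + 1)

    def fraction_densities(self) -> np.ndarray:
        """Bin midpoints indexed by fraction number: index 1 = densest."""
        edges = self.fraction_edges()
        mids = (edges[:-1] + edges[1:]) / 2.0
        return mids[::-1]


def buoyant_density(gc: float, atom_fraction_excess: float, cfg: SimConfig) -> float:
    """Band center from GC content and ¹⁵N atom-fraction excess."""
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    return cfg.gc_intercept + cfg.gc_slope * gc + atom_fraction_excess * cfg.delta_max_15n


def _band_mass(center: float, cfg: SimConfig) -> np.ndarray:
    """Gaussian band mass per fraction (indexed like fraction_densities)."""
    edges = cfg.fraction_edges()
    if center - 3 * cfg.band_sd < cfg.density_min or center + 3 * cfg.band_sd > cfg.density_max:
        warnings.warn(
            f"band truncated: center {center:.4f} ± 3×{cfg.band_sd} g/ml exceeds the "
            f"gradient window [{cfg.density_min}, {cfg.density_max}]",
            stacklevel=3,
        )
    mass = np.diff(norm.cdf(edges, loc=center, scale=cfg.band_sd))
    return mass[::-1]  # fraction 1 = densest


def _gradient_rng(cfg: SimConfig, treatment_index: int, side: int) -> np.random.Generator:
    # per-gradient substream: adding a treatment never perturbs earlier gradients
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, treatment_index, side]))


def simulate_gradient(
    community: list[SimOtu],
    treatment: str,
    cfg: SimConfig,
    gradient_id: str,
    rng: np.random.Generator,
) -> tuple[gio.GradientRun, pd.DataFrame]:
    """Band a community, collect fractions, select a window, and sample reads.

    Returns the gradient's fraction metadata (with ``sequenced`` flags on the
    selected window) and a reads DataFrame (OTU × sequenced fraction index).
    ``treatment`` is "control" or "labeled"; controls band with zero excess.
    """
    if not community:
        raise ValueError("community is empty")
    labeled = treatment == "labeled"
    total_ab = sum(o.rel_abundance for o in community)
    if abs(total_ab - 1.0) > 1e-6:
        raise ValueError(f"community abundances sum to {total_ab}, not 1")

    mass = np.zeros((len(community), cfg.n_fractions))
    for i, otu in enumerate(community):
        for sub in otu.components(labeled):
            center = buoyant_density(otu.gc_content, sub.atom_fraction_excess, cfg)
            mass[i] += sub.weight * _band_mass(center, cfg)

    abundances = np.array([o.rel_abundance for o in community])
    frac_dna = abundances @ mass  # community DNA mass per fraction
    noise = rng.lognormal(mean=0.0, sigma=cfg.dna_noise_sigma, size=cfg.n_fractions)
    dna_ng = TOTAL_DNA_NG * frac_dna / frac_dna.sum() * noise

    densities = cfg.fraction_densities()
    fractions = [
        gio.FractionRecord(
            gradient_id=gradient_id,
            fraction_index=i + 1,
            density=float(densities[i]),
            dna_quantity=float(dna_ng[i]),
            sequenced=False,
        )
        for i in range(cfg.n_fractions)
    ]
    run = gio.GradientRun(gradient_id=gradient_id, fractions=fractions, treatment=treatment)
    run = gio.select_fractions(run, n=cfg.n_select_fractions)

    seq_idx = np.array([f.fraction_index - 1 for f in run.sequenced_fractions])
    expected = (abundances[:, None] * mass)[:, seq_idx]
    p = expected.ravel() / expected.sum()
    counts = rng.multinomial(cfg.reads_per_gradient, p).reshape(expected.shape)
    reads = pd.DataFrame(
        counts,
        index=[o.otu_id for o in community],
        columns=[f.fraction_index for f in run.sequenced_fractions],
    )
    return run, reads


@dataclass(frozen=True)
class TreatmentSpec:
    """Per-treatment labeling design applied to the base community.

    ``excess`` maps otu_id to either an atom-fraction excess or a list of
    (weight, excess) subpopulations; missing OTUs stay unlabeled.
    """

    name: str
    substrate: str = "nitrate"
    excess: dict[str, float | list[tuple[float, float]]] = field(default_factory=dict)


@dataclass
class SimOutput:
    runs: list[gio.GradientRun]
    table: gio.OtuCountTable
    taxonomy: gio.TaxonomyMap
    manifest: gio.PairManifest
    truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _apply_treatment(community: list[SimOtu], spec: TreatmentSpec) -> list[SimOtu]:
    out = []
    for otu in community:
        exc = spec.excess.get(otu.otu_id, 0.0)
        if isinstance(exc, (list, tuple)):
            subs = [SubPop(w, e) for w, e in exc]
            out.append(
                SimOtu(otu.otu_id, otu.gc_content, otu.rel_abundance, 0.0, subs, otu.lineage)
            )
        else:
            out.append(
                SimOtu(otu.otu_id, otu.gc_content, otu.rel_abundance, float(exc), None, otu.lineage)
            )
    return out


def _truth_rows(community: list[SimOtu], spec: TreatmentSpec, cfg: SimConfig) -> list[dict]:
    rows = []
    for otu in community:
        control_center = buoyant_density(otu.gc_content, 0.0, cfg)
        comps = otu.components(labeled=True)
        dominant = max(comps, key=lambda s: s.weight)
        centers = [buoyant_density(otu.gc_content, s.atom_fraction_excess, cfg) for s in comps]
        rows.append(
            {
                "otu_id": otu.otu_id,
                "treatment": spec.name,
                "true_center_control": control_center,
                "true_center_labeled": buoyant_density(
                    otu.gc_content, dominant.atom_fraction_excess, cfg
                ),
                "true_shift": dominant.atom_fraction_excess * cfg.delta_max_15n,
                "all_labeled_centers": ";".join(f"{c:.6f}" for c in centers),
            }
        )
    return rows


def generate_paired_experiment(
    community: list[SimOtu],
    treatments: list[TreatmentSpec],
    cfg: SimConfig,
    outdir: str | Path | None = None,
) -> SimOutput:
    """Simulate control+labeled gradient pairs for each treatment.

    Writes (when ``outdir`` is given) the four pipeline input files plus
    ``truth.tsv``. Gradient ids are ``g_<treatment>_{14N,15N}``; the null
    treatment for LOD calibration is the first treatment named "LNT" if
    present, else the first treatment whose name contains "null".
    """
    runs: list[gio.GradientRun] = []
    tables: list[pd.DataFrame] = []
    entries: list[gio.PairEntry] = []
    truth_rows: list[dict] = []
    for t_idx, spec in enumerate(treatments):
        treated = _apply_treatment(community, spec)
        gid_c = f"g_{spec.name}_14N"
        gid_l = f"g_{spec.name}_15N"
        run_c, reads_c = simulate_gradient(treated, "control", cfg, gid_c, _gradient_rng(cfg, t_idx, 0))
        run_l, reads_l = simulate_gradient(treated, "labeled", cfg, gid_l, _gradient_rng(cfg, t_idx, 1))
        run_c.substrate = run_l.substrate = spec.substrate
        runs += [run_c, run_l]
        for gid, reads in ((gid_c, reads_c), (gid_l, reads_l)):
            df = reads.copy()
            df.columns = pd.MultiIndex.from_tuples(
                [(gid, int(c)) for c in df.columns], names=["gradient_id", "fraction_index"]
            )
            tables.append(df)
        entries.append(gio.PairEntry(gid_l, gid_c, spec.name))
        truth_rows += _truth_rows(treated, spec, cfg)

    null_name = next(
        (s.name for s in treatments if s.name == "LNT"),
        next((s.name for s in treatments if "null" in s.name.lower()), ""),
    )
    table = gio.OtuCountTable(pd.concat(tables, axis=1))
    taxonomy = gio.TaxonomyMap(
        {o.otu_id: tuple(o.lineage.split(";")) for o in community}
    )
    manifest = gio.PairManifest(entries=entries, null_treatment_name=null_name)
    truth = pd.DataFrame(truth_rows)

    out = SimOutput(runs=runs, table=table, taxonomy=taxonomy, manifest=manifest, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "metadata": outdir / "fractions.csv",
            "counts": outdir / "otu_counts.tsv",
            "taxonomy": outdir / "taxonomy.tsv",
            "manifest": outdir / "manifest.yaml",
            "truth": outdir / "truth.tsv",
        }
        gio.write_fraction_metadata(runs, paths["metadata"])
        gio.write_otu_table(table, paths["counts"])
        gio.write_taxonomy(taxonomy, paths["taxonomy"])
        gio.write_manifest(manifest, paths["manifest"])
        truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6f")
        out.paths = paths
    return out


# ---------------------------------------------------------------------------
# canonical study-like designs

MARINE_LINEAGES = [
    "Bacteria;Proteobacteria;Alphaproteobacteria;SAR11_clade;Surface_1;unclassified",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae;Roseobacter",
    "Bacteria;Proteobacteria;Gammaproteobacteria;SAR86_clade;unclassified;unclassified",
    "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae;unclassified",
    "Bacteria;Cyanobacteria;Cyanobacteria;SubsectionI;FamilyI;Prochlorococcus",
    "Bacteria;Cyanobacteria;Cyanobacteria;SubsectionI;FamilyI;Synechococcus",
    "Archaea;Euryarchaeota;Thermoplasmata;Marine_Group_II;unclassified;unclassified",
]


def example_community(
    n_otus: int = 100,
    rng: np.random.Generator | None = None,
    gc_mean: float = 0.5,
    gc_sd: float = 0.05,
) -> list[SimOtu]:
    """An even marine-like community with GC ~ N(gc_mean, gc_sd²) clipped to [0.3, 0.7]."""
    rng = rng or np.random.default_rng(0)
    gcs = np.clip(rng.normal(gc_mean, gc_sd, size=n_otus), 0.3, 0.7)
    width = len(str(n_otus))
    return [
        SimOtu(
            otu_id=f"OTU{i + 1:0{width}d}",
            gc_content=float(gcs[i]),
            rel_abundance=1.0 / n_otus,
            lineage=MARINE_LINEAGES[i % len(MARINE_LINEAGES)],
        )
        for i in range(n_otus)
    ]


def null_excess(otu_ids: list[str], rng: np.random.Generator, mean: float = 0.005,
                cap: float = 0.12) -> dict[str, float]:
    """Null-treatment labeling: essentially unlabeled, imposed shifts < 0.002 g/ml.

    Excess ~ Exponential(mean) capped at ``cap`` (cap × 0.016 = 0.00192 g/ml),
    emulating an incubation whose labeling stays below detectability.
    """
    return {o: float(min(rng.exponential(mean), cap)) for o in otu_ids}


def labeled_excess(
    otu_ids: list[str],
    rng: np.random.Generator,
    fraction_labeled: float = 0.5,
    excess_range: tuple[float, float] = (0.3, 0.8),
) -> dict[str, float]:
    """Label a fixed fraction of OTUs with excess drawn uniformly from ``excess_range``.

    The first ``fraction_labeled`` share of OTU ids (list order) is labeled;
    the rest stay at zero, giving a known ground truth for recovery tests.
    """
    n_lab = int(round(fraction_labeled * len(otu_ids)))
    lo, hi = excess_range
    return {o: float(rng.uniform(lo, hi)) for o in otu_ids[:n_lab]}
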
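"""Closed-form isotope mass-balance calculators for ¹⁵N SIP experiments.

Everything here is algebra on pool sizes, atom fractions and rates; no data
files are involved. The calculators answer three planning/interpretation
questions for a stable-isotope-probing incubation:

* what is the atom% ¹⁵N of the substrate pool once a labeled amendment is
  mixed into the ambient (unlabeled) pool;
* given that pool and semiconservative DNA replication, how labeled can bulk
  DNA become after ``g`` doublings;
* could cross-feeding (release and re-uptake of label via PON/DON/ammonium)
  plausibly produce a detectable secondary signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Natural abundance of ¹⁵N as an atom fraction.
X_NAT_15N = 0.003663

#: Maximum buoyant-density gain of fully ¹⁵N-labeled DNA (g ml⁻¹).
DELTA_MAX_15N = 0.016

#: Maximum buoyant-density gain of fully ¹³C-labeled DNA (g ml⁻¹).
DELTA_MAX_13C = 0.036


@dataclass(frozen=True)
class SubstratePool:
    """An amended substrate pool: labeled addition mixed into ambient stock.

    Attributes
    ----------
    c_s : float
        Added labeled substrate concentration (μM).
    c_a : float
        Ambient unlabeled concentration (μM).
    x_label : float
        Atom fraction ¹⁵N of the labeled stock.
    x_nat : float
        Natural-abundance atom fraction.
    atom_percent : float
        Atom% ¹⁵N of the mixed pool.
    cs_ca_ratio : float
        Ratio of added to ambient concentration (Cs:Ca).
    """

    c_s: float
    c_a: float
    x_label: float = 0.98
    x_nat: float = X_NAT_15N
    atom_percent: float = field(init=False)
    cs_ca_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if self.c_a <= 0:
            raise ValueError("ambient concentration c_a must be > 0 (Cs:Ca undefined otherwise)")
        if self.c_s < 0:
            raise ValueError("added substrate concentration c_s must be >= 0")
        if not (self.x_nat <= self.x_label <= 1.0):
            raise ValueError("need x_nat <= x_label <= 1")
        ap = 100.0 * (self.x_label * self.c_s + self.x_nat * self.c_a) / (self.c_s + self.c_a)
        object.__setattr__(self, "atom_percent", ap)
        object.__setattr__(self, "cs_ca_ratio", self.c_s / self.c_a)


def pool_atom_percent(
    c_s: float,
    c_a: float,
    x_label: float = 0.98,
    x_nat: float = X_NAT_15N,
) -> SubstratePool:
    """Two-pool isotope mixing: atom% ¹⁵N of amendment + ambient.

    atom% = 100 · (x_label·c_s + x_nat·c_a) / (c_s + c_a).  Values are kept
    at full precision; round only for reporting.
    """
    return SubstratePool(c_s=c_s, c_a=c_a, x_label=x_label, x_nat=x_nat)


@dataclass(frozen=True)
class LabelingModel:
    """Expected bulk-DNA atom% ¹⁵N after ``doublings`` semiconservative rounds.

    Each doubling replaces half of the remaining unlabeled strands with
    strands built from the pool, so the DNA atom% relaxes from natural
    abundance toward the pool value:

        dna = pool·(1 − 2⁻ᵍ) + 100·x_nat·2⁻ᵍ
    """

    pool_atom_percent: float
    doublings: float
    x_nat: float = X_NAT_15N
    dna_atom_percent: float = field(init=False)

    def __post_init__(self) -> None:
        if self.doublings < 0:
            raise ValueError("doublings must be >= 0")
        w = 2.0 ** (-self.doublings)
        dna = self.pool_atom_percent * (1.0 - w) + 100.0 * self.x_nat * w
        object.__setattr__(self, "dna_atom_percent", dna)


def expected_dna_labeling(
    pool: SubstratePool | float,
    doublings: float,
    x_nat: float = X_NAT_15N,
) -> float:
    """Upper bound on bulk-DNA atom% ¹⁵N after ``doublings`` doublings.

    Assumes the amended substrate is the organism's sole N source, so this
    is a ceiling for real assimilation. ``pool`` may be a
    :class:`SubstratePool` or an atom% value.
    """
    pool_pct = pool.atom_percent if isinstance(pool, SubstratePool) else float(pool)
    return LabelingModel(pool_pct, doublings, x_nat=x_nat).dna_atom_percent


@dataclass(frozen=True)
class DensityGainModel:
    """Full-label buoyant-density gains per isotope (g ml⁻¹).

    ¹⁵N substitution adds roughly half the density that ¹³C substitution
    does, which is why ¹⁵N SIP needs per-taxon profile resolution.
    """

    delta_max_15n: float = DELTA_MAX_15N
    delta_max_13c: float = DELTA_MAX_13C

    def delta_max(self, isotope: str) -> float:
        key = isotope.upper().replace("^", "")
        if key in ("15N", "N15"):
            return self.delta_max_15n
        if key in ("13C", "C13"):
            return self.delta_max_13c
        raise ValueError(f"unknown isotope {isotope!r}; expected '15N' or '13C'")


def expected_density_shift(
    atom_fraction_excess: float,
    isotope: str = "15N",
    model: DensityGainModel | None = None,
) -> float:
    """Predicted buoyant-density shift (g ml⁻¹) at a given atom-fraction excess.

    Linear in excess: shift = excess × delta_max(isotope).
    """
    if not (0.0 <= atom_fraction_excess <= 1.0):
        raise ValueError("atom_fraction_excess must lie in [0, 1]")
    model = model or DensityGainModel()
    return atom_fraction_excess * model.delta_max(isotope)


@dataclass(frozen=True)
class CrossFeedBudget:
    """Mass-balance bound on secondary (cross-fed) ¹⁵N labeling.

    Primary uptake enriches PON over the incubation; the enriched PON
    releases DON and ammonium at fixed rates; a competing consumer taking up
    ammonium at ``competing_uptake_rate`` could at most assimilate the
    released label. ``secondary_fraction`` expresses that released label as
    a percentage of the competitor's total N uptake.
    """

    primary_uptake_rate: float  # μmol N L⁻¹ h⁻¹
    duration: float  # h
    pon: float  # μM N
    release_rates: dict[str, float]  # μmol N L⁻¹ h⁻¹ per released species
    competing_uptake_rate: float  # μmol N L⁻¹ h⁻¹
    pon_label_fraction: float = field(init=False)
    labeled_release: dict[str, float] = field(init=False)  # μM per species
    secondary_fraction: float = field(init=False)  # %

    def __post_init__(self) -> None:
        if self.pon <= 0 or self.duration <= 0:
            raise ValueError("pon and duration must be > 0")
        if self.competing_uptake_rate <= 0:
            raise ValueError("competing uptake rate must be > 0 (secondary fraction undefined)")
        if self.primary_uptake_rate < 0 or any(r < 0 for r in self.release_rates.values()):
            raise ValueError("rates must be >= 0")
        frac = min(1.0, self.primary_uptake_rate * self.duration / self.pon)
        released = {s: r * self.duration * frac for s, r in self.release_rates.items()}
        sec = 100.0 * sum(released.values()) / (self.competing_uptake_rate * self.duration)
        object.__setattr__(self, "pon_label_fraction", frac)
        object.__setattr__(self, "labeled_release", released)
        object.__setattr__(self, "secondary_fraction", sec)

    def verdict(self, negligibility_threshold: float = 10.0) -> str:
        """One-line plausibility verdict against a percentage threshold."""
        word = "negligible" if self.secondary_fraction < negligibility_threshold else "NON-negligible"
        return (
            f"secondary label is {self.secondary_fraction:.1f}% of competing N uptake "
            f"({word} at the {negligibility_threshold:.0f}% threshold)"
        )


def cross_feeding_budget(
    uptake: float,
    pon: float,
    duration: float,
    releases: dict[str, float],
    competing_uptake: float,
) -> CrossFeedBudget:
    """Build the cross-feeding plausibility budget from measured rates.

    Parameters are the primary substrate uptake rate (μmol N L⁻¹ h⁻¹), the
    PON standing stock (μM N), the incubation length (h), per-species
    release rates from PON, and the competing consumer's uptake rate.
    """
    return CrossFeedBudget(
        primary_uptake_rate=uptake,
        duration=duration,
        pon=pon,
        release_rates=dict(releases),
        competing_uptake_rate=competing_uptake,
    )
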
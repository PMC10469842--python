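"""Forward simulation of dual-isotope qSIP gradient fractionation.

Each taxon's DNA bands isopycnically in the CsCl gradient as a Gaussian
centred on its expected buoyant density — determined by GC content and
by how much heavy isotope it incorporated — with a common band width
(diffusion-dominated banding). The gradient is cut into raw fractions,
composited into a smaller number of density bins, and sequenced:
multinomial read counts per fraction, plus a per-fraction DNA
concentration derived from the simulated DNA mass with lognormal
measurement error. Because every taxon's GC and atom fraction excess
are known, the simulator provides exact ground truth for the whole
downstream estimation chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import CARBON_13, NITROGEN_15, IsotopeConstants
from .qsip import FractionRecord, molecular_weights


@dataclass(frozen=True)
class TaxonTruth:
    """Ground truth for one synthetic taxon."""

    taxon_id: str
    gc: float
    rel_abundance: float
    true_afe_13c: float
    true_afe_15n: float
    domain_label: str = "bacteria"
    guild_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc outside [0, 1]")
        for a in (self.true_afe_13c, self.true_afe_15n):
            if not 0.0 <= a <= 0.99:
                raise ValueError("true AFE outside [0, 0.99]")


@dataclass(frozen=True)
class GradientDesign:
    """Geometry and depth of the simulated fractionation.

    Defaults mirror the study design being emulated: raw gradients cut
    into ~two dozen fractions spanning 1.665-1.784 g/mL around a mean
    gradient density of 1.730 g/mL, composited into nine density bins.
    """

    n_raw_fractions: int = 24
    n_composite: int = 9
    density_min: float = 1.665
    density_max: float = 1.784
    mean_density: float = 1.730
    band_sigma: float = 0.006  # g/mL
    reads_per_fraction: int = 20_000
    dna_total: float = 1000.0  # ng loaded on the gradient
    fraction_volume: float = 40.0  # uL each composite is resuspended in
    dna_conc_cv: float = 0.10  # lognormal CV of concentration measurement

    def __post_init__(self) -> None:
        if not self.density_min < self.mean_density < self.density_max:
            raise ValueError("mean density outside gradient range")
        if self.n_composite > self.n_raw_fractions:
            raise ValueError("more composite bins than raw fractions")

    @property
    def raw_edges(self) -> np.ndarray:
        return np.linspace(self.density_min, self.density_max, self.n_raw_fractions + 1)

    @property
    def raw_centers(self) -> np.ndarray:
        e = self.raw_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def composite_edges(self) -> np.ndarray:
        return np.linspace(self.density_min, self.density_max, self.n_composite + 1)

    def composite_assignment(self) -> np.ndarray:
        """Composite bin index of each raw fraction (half-open bins, last closed)."""
        idx = np.searchsorted(self.composite_edges, self.raw_centers, side="right") - 1
        return np.clip(idx, 0, self.n_composite - 1)


def expected_wad(
    gc: float, true_afe: float, k: IsotopeConstants
) -> float:
    """Buoyant density at which a taxon with this GC and AFE bands.

    Exact inverse of the AFE estimation chain: the labeled molecular
    weight is interpolated between light and fully-heavy according to
    AFE / (1 - natural abundance), and density scales proportionally.
    """
    if not 0.0 <= true_afe <= 1.0 - k.natural_abundance:
        raise ValueError(f"true AFE {true_afe} outside [0, 1 - a]")
    m_light, m_heavymax = molecular_weights(gc, k)
    m_lab = m_light + (true_afe / (1.0 - k.natural_abundance)) * (m_heavymax - m_light)
    wad_light = k.schildkraut_intercept + k.schildkraut_slope * gc
    return wad_light * (m_lab / m_light)


def band_masses(
    center: float, design: GradientDesign, rel_abundance: float = 1.0
) -> np.ndarray:
    """Expected DNA mass of one taxon in each raw fraction.

    Integral of the Gaussian band over each fraction's density
    interval; mass banding outside the collected window is lost.
    """
    cdf = stats.norm.cdf(design.raw_edges, loc=center, scale=design.band_sigma)
    return rel_abundance * np.diff(cdf)


def composite_profile(
    raw_masses: np.ndarray, design: GradientDesign
) -> np.ndarray:
    """Sum raw-fraction masses into the composite density bins."""
    assign = design.composite_assignment()
    out = np.zeros((raw_masses.shape[0], design.n_composite))
    for b in range(design.n_composite):
        out[:, b] = raw_masses[:, assign == b].sum(axis=1)
    return out


def composite_densities(
    raw_masses_total: np.ndarray, design: GradientDesign
) -> np.ndarray:
    """Measured density of each composite fraction.

    DNA-mass-weighted mean of the member raw fractions' densities;
    an empty composite reports its bin midpoint.
    """
    assign = design.composite_assignment()
    centers = design.raw_centers
    edges = design.composite_edges
    dens = np.empty(design.n_composite)
    for b in range(design.n_composite):
        sel = assign == b
        m = raw_masses_total[sel]
        if m.sum() > 0:
            dens[b] = np.average(centers[sel], weights=m)
        else:
            dens[b] = 0.5 * (edges[b] + edges[b + 1])
    return dens


def simulate_profile(
    taxon: TaxonTruth, design: GradientDesign, isotope: str
) -> np.ndarray:
    """Noiseless per-composite-fraction mass weights for one taxon."""
    k, afe = _isotope_and_afe(taxon, isotope)
    center = expected_wad(taxon.gc, afe, k)
    raw = band_masses(center, design, taxon.rel_abundance)
    return composite_profile(raw[None, :], design)[0]


def _isotope_and_afe(taxon: TaxonTruth, isotope: str) -> tuple[IsotopeConstants, float]:
    if isotope == "13C":
        return CARBON_13, taxon.true_afe_13c
    if isotope == "15N":
        return NITROGEN_15, taxon.true_afe_15n
    if isotope == "unlabeled":
        return CARBON_13, 0.0  # constants only set the band position via GC
    raise ValueError(f"unknown isotope {isotope!r}")


def simulate_counts(
    mass_weights: np.ndarray,
    reads_per_fraction: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial read counts per fraction, proportional to DNA mass.

    ``mass_weights`` is taxa x fractions; fractions with zero total
    mass yield zero counts.
    """
    w = np.asarray(mass_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative mass weights")
    counts = np.zeros_like(w, dtype=np.int64)
    for f in range(w.shape[1]):
        total = w[:, f].sum()
        if total > 0:
            counts[:, f] = rng.multinomial(reads_per_fraction, w[:, f] / total)
    return counts


def simulate_sample(
    truths: Sequence[TaxonTruth],
    design: GradientDesign,
    isotope: str,
    sample_id: str,
    rng: np.random.Generator,
    noiseless: bool = False,
) -> list[FractionRecord]:
    """Fractionate and sequence one sample of the community.

    With ``noiseless=True`` the multinomial and concentration noise are
    replaced by their expectations (counts scaled to large integers),
    leaving only the discreteness of the density bins.
    """
    raw = np.stack(
        [
            band_masses(
                expected_wad(t.gc, _isotope_and_afe(t, isotope)[1],
                             _isotope_and_afe(t, isotope)[0]),
                design,
                t.rel_abundance,
            )
            for t in truths
        ]
    )
    comp = composite_profile(raw, design)
    dens = composite_densities(raw.sum(axis=0), design)

    mass_per_fraction = comp.sum(axis=0)  # relative units, community sums to <= 1
    dna_ng = design.dna_total * mass_per_fraction
    if noiseless:
        # expectations: exact relative counts, no concentration error
        scale = 1e8
        counts = np.rint(comp / max(comp.sum(), 1e-300) * scale).astype(np.int64)
        conc = dna_ng / design.fraction_volume
    else:
        counts = simulate_counts(comp, design.reads_per_fraction, rng)
        sigma = np.sqrt(np.log1p(design.dna_conc_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=dens.size)
        conc = dna_ng / design.fraction_volume * noise

    records = []
    for f in range(design.n_composite):
        records.append(
            FractionRecord(
                sample_id=sample_id,
                fraction_index=f + 1,
                density=float(dens[f]),
                dna_conc=float(conc[f]),
                counts={
                    t.taxon_id: int(counts[i, f])
                    for i, t in enumerate(truths)
                    if counts[i, f] > 0
                },
            )
        )
    return records


# ---------------------------------------------------------------------------
# Study-level generation


@dataclass
class StudyScenario:
    """Community and effect-size settings for a full simulated study.

    Mean true AFE is configured per necromass type and stage; low
    melanin supports stronger enrichment than high, and enrichment
    declines from the earlier to the later stage of decomposition.
    """

    n_bacteria: int = 200
    n_fungi: int = 100
    gc_range: tuple[float, float] = (0.3, 0.7)
    afe_beta_a: float = 2.0
    mean_afe_13c: dict = field(
        default_factory=lambda: {"low": 0.35, "high": 0.20}
    )
    mean_afe_15n: dict = field(
        default_factory=lambda: {"low": 0.30, "high": 0.18}
    )
    later_attenuation: float = 0.7  # multiplier on mean AFE at the later stage
    abundance_lognorm_sigma: float = 1.0
    # coupled C/N uptake: Gaussian-copula correlation between a taxon's
    # true 13C and 15N AFE, and the probability that a taxon assimilates
    # each element at all (inactive taxa have true AFE 0 for that isotope)
    cn_copula_rho: float = 0.7
    p_active_13c: float = 0.95
    p_active_15n: float = 0.70


@dataclass
class SyntheticDataset:
    truths: pd.DataFrame
    records: dict[str, list[FractionRecord]]
    manifest: pd.DataFrame


def _draw_afe(
    rng: np.random.Generator, n: int, mean: float, beta_a: float, cap: float = 0.99
) -> np.ndarray:
    """Beta-distributed true AFE scaled to [0, cap] with the given mean."""
    m = mean / cap
    beta_b = beta_a * (1.0 - m) / m
    return cap * rng.beta(beta_a, beta_b, size=n)


def _draw_afe_pair(
    rng: np.random.Generator,
    n: int,
    mean_c: float,
    mean_n: float,
    beta_a: float,
    rho: float,
    cap: float = 0.99,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (13C, 15N) true AFE via a Gaussian copula over Beta marginals."""
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    u = stats.norm.cdf(z)
    out = []
    for col, mean in ((0, mean_c), (1, mean_n)):
        m = mean / cap
        beta_b = beta_a * (1.0 - m) / m
        out.append(cap * stats.beta.ppf(u[:, col], beta_a, beta_b))
    return out[0], out[1]


def generate_study(
    design: GradientDesign | None = None,
    scenario: StudyScenario | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate the full study: 2 necromass types x 3 isotope treatments
    x 2 stages, sharing one community whose true AFE varies by condition.

    Returns per-sample fraction records, a manifest pairing each labeled
    sample with the unlabeled sample of its condition, and a tidy truth
    table (one row per taxon x condition).
    """
    design = design or GradientDesign()
    scenario = scenario or StudyScenario()
    rng = np.random.default_rng(seed)

    n = scenario.n_bacteria + scenario.n_fungi
    domains = ["bacteria"] * scenario.n_bacteria + ["fungi"] * scenario.n_fungi
    ids = [f"OTU{i + 1:04d}" for i in range(n)]
    gc = rng.uniform(*scenario.gc_range, size=n)
    ab = rng.lognormal(0.0, scenario.abundance_lognorm_sigma, size=n)
    ab /= ab.sum()
    active_c = rng.random(n) < scenario.p_active_13c
    active_n = rng.random(n) < scenario.p_active_15n

    truth_rows = []
    records: dict[str, list[FractionRecord]] = {}
    manifest_rows = []
    for necromass in ("low", "high"):
        for stage in ("earlier", "later"):
            atten = 1.0 if stage == "earlier" else scenario.later_attenuation
            afe_c, afe_n = _draw_afe_pair(
                rng,
                n,
                scenario.mean_afe_13c[necromass] * atten,
                scenario.mean_afe_15n[necromass] * atten,
                scenario.afe_beta_a,
                scenario.cn_copula_rho,
            )
            afe_c = np.where(active_c, afe_c, 0.0)
            afe_n = np.where(active_n, afe_n, 0.0)
            truths = [
                TaxonTruth(ids[i], gc[i], ab[i], afe_c[i], afe_n[i], domains[i])
                for i in range(n)
            ]
            for i in range(n):
                truth_rows.append(
                    {
                        "taxon_id": ids[i],
                        "domain": domains[i],
                        "gc": gc[i],
                        "rel_abundance": ab[i],
                        "necromass_type": necromass,
                        "stage": stage,
                        "true_afe_13c": afe_c[i],
                        "true_afe_15n": afe_n[i],
                    }
                )
            unlabeled_id = f"{necromass}_{stage}_unlabeled"
            for isotope in ("unlabeled", "13C", "15N"):
                sample_id = f"{necromass}_{stage}_{isotope}"
                records[sample_id] = simulate_sample(
                    truths, design, isotope, sample_id, rng
                )
                manifest_rows.append(
                    {
                        "sample_id": sample_id,
                        "isotope": isotope,
                        "necromass_type": necromass,
                        "stage": stage,
                        "paired_unlabeled_id": ""
                        if isotope == "unlabeled"
                        else unlabeled_id,
                    }
                )
    return SyntheticDataset(
        truths=pd.DataFrame(truth_rows),
        records=records,
        manifest=pd.DataFrame(manifest_rows),
    )
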
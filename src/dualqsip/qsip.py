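"""Core qSIP estimation: density shift -> per-taxon atom fraction excess.

Quantitative stable-isotope probing infers how much heavy isotope each
taxon incorporated from the shift of its DNA's weighted average buoyant
density (WAD) between an unlabeled and a labeled sample fractionated on
a CsCl gradient:

1. per fraction, weight each taxon's relative read abundance by the
   fraction's DNA concentration (``y_f = p_f * D_f``);
2. WAD = sum(x_f * y_f) / sum(y_f) over fractions at densities x_f;
3. GC content from the unlabeled WAD via Schildkraut's relation;
4. light and maximally heavy molecular weights from GC;
5. the labeled molecular weight from the proportional density shift,
   ``M_lab = M_light * (WAD_lab / WAD_light)``;
6. atom fraction excess
   ``A = (M_lab - M_light) / (M_heavymax - M_light) * (1 - a)``,
   with ``a`` the natural abundance of the heavy isotope;
7. cap at the media maximum (0.99) and call a taxon enriched when the
   normalized AFE exceeds the retention threshold (0.10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import IsotopeConstants

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FractionRecord:
    """One density fraction of one sample."""

    sample_id: str
    fraction_index: int
    density: float  # g/mL
    dna_conc: float  # ng/uL
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.dna_conc < 0:
            raise ValueError(f"{self.sample_id}:{self.fraction_index}: dna_conc < 0")
        for taxon, c in self.counts.items():
            if c < 0:
                raise ValueError(
                    f"{self.sample_id}:{self.fraction_index}: negative count for {taxon}"
                )

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class WadEstimate:
    taxon_id: str
    sample_id: str
    wad: float


@dataclass(frozen=True)
class AfeEstimate:
    """Per taxon x isotope atom-fraction-excess estimate."""

    taxon_id: str
    isotope: str
    afe_raw: float
    afe_norm: float
    retained: bool
    gc: float
    wad_light: float
    wad_labeled: float
    gc_clamped: bool = False


@dataclass
class SkipReport:
    """Taxa that could not be estimated, with the reason."""

    rows: list[tuple[str, str]] = field(default_factory=list)

    def add(self, taxon_id: str, reason: str) -> None:
        self.rows.append((taxon_id, reason))
        logger.info("skipping %s: %s", taxon_id, reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["otu_id", "reason"])


def validate_sample(records: Sequence[FractionRecord]) -> list[FractionRecord]:
    """Order a sample's fractions by index and check density monotonicity."""
    recs = sorted(records, key=lambda r: r.fraction_index)
    if not recs:
        raise ValueError("sample has no fractions")
    sample_ids = {r.sample_id for r in recs}
    if len(sample_ids) != 1:
        raise ValueError(f"records from multiple samples: {sorted(sample_ids)}")
    dens = [r.density for r in recs]
    if any(b <= a for a, b in zip(dens, dens[1:])):
        raise ValueError(
            f"densities not strictly increasing with fraction index in "
            f"{recs[0].sample_id}: {dens}"
        )
    return recs


def weighted_abundance(counts_f: float, total_f: float, dna_conc_f: float) -> float:
    """DNA-concentration-weighted abundance of a taxon in one fraction.

    Relative read abundance within the fraction times the fraction's
    DNA concentration; a fraction with zero total reads contributes 0.
    """
    if counts_f < 0 or total_f < 0 or dna_conc_f < 0:
        raise ValueError("weighted_abundance: negative input")
    if total_f == 0:
        if counts_f != 0:
            raise ValueError("counts positive but fraction total is zero")
        return 0.0
    return (counts_f / total_f) * dna_conc_f


def taxon_profile(records: Sequence[FractionRecord], taxon_id: str) -> np.ndarray:
    """Weighted-abundance vector y_f of one taxon across a sample's fractions."""
    return np.array(
        [
            weighted_abundance(r.counts.get(taxon_id, 0), r.total_reads, r.dna_conc)
            for r in records
        ]
    )


def weighted_average_density(
    weighted_abundances: np.ndarray, densities: np.ndarray
) -> float:
    """Abundance-weighted mean buoyant density of one taxon's DNA.

    Raises ``ValueError`` if the profile carries no mass (no WAD exists).
    """
    y = np.asarray(weighted_abundances, dtype=float)
    x = np.asarray(densities, dtype=float)
    if y.shape != x.shape:
        raise ValueError("profile and density vectors differ in length")
    if np.any(y < 0):
        raise ValueError("negative weighted abundance")
    total = y.sum()
    if total <= 0:
        raise ValueError("all-zero profile: no WAD")
    return float(np.dot(x, y) / total)


def gc_from_wad(wad_light: float, k: IsotopeConstants) -> tuple[float, bool]:
    """GC content implied by the unlabeled WAD (Schildkraut inverse).

    Returns ``(gc, clamped)``; noisy WADs can imply GC outside [0, 1],
    in which case the value is clamped and flagged.
    """
    gc = (wad_light - k.schildkraut_intercept) / k.schildkraut_slope
    if 0.0 <= gc <= 1.0:
        return gc, False
    logger.warning("GC %.4f from WAD %.5f outside [0,1]; clamped", gc, wad_light)
    return min(max(gc, 0.0), 1.0), True


def molecular_weights(gc: float, k: IsotopeConstants) -> tuple[float, float]:
    """Light and fully-heavy mean nucleotide molecular weights (g/mol)."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc {gc} outside [0, 1]")
    m_light = k.mw_slope * gc + k.mw_intercept
    m_heavymax = m_light + k.shift_slope * gc + k.shift_intercept
    return m_light, m_heavymax


def atom_fraction_excess(
    wad_light: float, wad_labeled: float, k: IsotopeConstants, gc: float | None = None
) -> float:
    """Raw atom fraction excess from the unlabeled/labeled WAD pair.

    ``gc`` defaults to the value implied by ``wad_light``; it may be
    supplied when known independently (e.g. noiseless simulations).
    """
    if gc is None:
        gc, _ = gc_from_wad(wad_light, k)
    m_light, m_heavymax = molecular_weights(gc, k)
    m_lab = m_light * (wad_labeled / wad_light)
    return (m_lab - m_light) / (m_heavymax - m_light) * (1.0 - k.natural_abundance)


def normalize_afe(afe_raw: float, k: IsotopeConstants) -> float:
    """Cap the raw AFE at the media maximum; negatives pass through."""
    return min(afe_raw, k.label_cap)


def filter_enriched(
    estimates: Iterable[AfeEstimate], k: IsotopeConstants
) -> list[AfeEstimate]:
    """Taxa whose normalized AFE strictly exceeds the retention threshold."""
    return [e for e in estimates if e.afe_norm > k.retention_threshold]


def estimate_afe_table(
    labeled: Sequence[FractionRecord],
    unlabeled: Sequence[FractionRecord],
    k: IsotopeConstants,
) -> tuple[list[AfeEstimate], SkipReport]:
    """Run the full estimation chain for every taxon in both samples.

    Taxa absent (zero weighted abundance) from either sample are listed
    in the skip report instead of the estimate table. The two samples
    keep their own measured density axes; no interpolation is done.
    """
    lab = validate_sample(labeled)
    unlab = validate_sample(unlabeled)
    dens_lab = np.array([r.density for r in lab])
    dens_unlab = np.array([r.density for r in unlab])

    taxa_lab = set().union(*(r.counts.keys() for r in lab))
    taxa_unlab = set().union(*(r.counts.keys() for r in unlab))

    skips = SkipReport()
    estimates: list[AfeEstimate] = []
    for taxon in sorted(taxa_lab | taxa_unlab):
        y_lab = taxon_profile(lab, taxon)
        y_unlab = taxon_profile(unlab, taxon)
        present_lab, present_unlab = y_lab.sum() > 0, y_unlab.sum() > 0
        if not (present_lab and present_unlab):
            where = (
                "labeled sample only"
                if present_lab
                else "unlabeled sample only"
                if present_unlab
                else "no reads in either sample"
            )
            skips.add(taxon, f"present in {where}")
            continue
        wad_lab = weighted_average_density(y_lab, dens_lab)
        wad_light = weighted_average_density(y_unlab, dens_unlab)
        gc, clamped = gc_from_wad(wad_light, k)
        raw = atom_fraction_excess(wad_light, wad_lab, k, gc=gc)
        norm = normalize_afe(raw, k)
        estimates.append(
            AfeEstimate(
                taxon_id=taxon,
                isotope=k.isotope,
                afe_raw=raw,
                afe_norm=norm,
                retained=norm > k.retention_threshold,
                gc=gc,
                wad_light=wad_light,
                wad_labeled=wad_lab,
                gc_clamped=clamped,
            )
        )
    if not estimates:
        logger.warning("no overlapping taxa between labeled and unlabeled samples")
    return estimates, skips


def afe_table_to_frame(estimates: Sequence[AfeEstimate]) -> pd.DataFrame:
    """AFE estimates as the standard output table (percent-scale column)."""
    return pd.DataFrame(
        {
            "otu_id": [e.taxon_id for e in estimates],
            "isotope": [e.isotope for e in estimates],
            "gc": [e.gc for e in estimates],
            "wad_light": [e.wad_light for e in estimates],
            "wad_labeled": [e.wad_labeled for e in estimates],
            "afe_raw": [e.afe_raw for e in estimates],
            "afe_norm_percent": [100.0 * e.afe_norm for e in estimates],
            "retained": [e.retained for e in estimates],
            "gc_clamped": [e.gc_clamped for e in estimates],
        }
    )
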
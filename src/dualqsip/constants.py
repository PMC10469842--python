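"""Physical constants of the qSIP density-shift calculation.

The calculation rests on two empirical linear relationships for
double-stranded DNA in CsCl:

* Schildkraut's relation between buoyant density and GC content,
  ``rho = 1.66 + 0.098 * GC`` (g/mL), used to infer GC from the
  unlabeled weighted average density; and
* the mean nucleotide molecular weight as a function of GC,
  ``M = 0.496 * GC + 307.691`` (g/mol), together with the
  isotope-specific increase in molecular weight when every C (or N)
  atom is replaced by its heavy isotope.

Natural abundances: 1.111233% for 13C and 0.3663% for 15N.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

SCHILDKRAUT_INTERCEPT = 1.66  # g/mL, density of GC-free DNA
SCHILDKRAUT_SLOPE = 0.098  # g/mL per unit GC fraction
MW_SLOPE = 0.496  # g/mol per unit GC fraction
MW_INTERCEPT = 307.691  # g/mol, mean nucleotide MW at GC = 0


@dataclass(frozen=True)
class IsotopeConstants:
    """Constants needed to turn a density shift into atom fraction excess.

    Parameters
    ----------
    isotope
        ``"13C"`` or ``"15N"``.
    natural_abundance
        Atom fraction of the heavy isotope in unlabeled material.
    shift_slope, shift_intercept
        Coefficients of the GC-dependent molecular-weight gain
        ``M_heavymax - M_light = shift_slope * GC + shift_intercept``
        (g/mol) when the element is fully substituted by the heavy
        isotope.
    label_cap
        Maximum attainable atom fraction excess given the growth-media
        enrichment (0.99 for 99%-enriched substrate).
    retention_threshold
        Normalized-AFE cutoff above which a taxon is called enriched
        (strict inequality).
    """

    isotope: str
    natural_abundance: float
    shift_slope: float
    shift_intercept: float
    label_cap: float = 0.99
    retention_threshold: float = 0.10
    schildkraut_intercept: float = SCHILDKRAUT_INTERCEPT
    schildkraut_slope: float = SCHILDKRAUT_SLOPE
    mw_slope: float = MW_SLOPE
    mw_intercept: float = MW_INTERCEPT

    def __post_init__(self) -> None:
        if not 0.0 < self.natural_abundance < 0.02:
            raise ValueError(
                f"natural abundance {self.natural_abundance} outside (0, 0.02)"
            )
        if not 0.0 < self.label_cap <= 1.0:
            raise ValueError(f"label cap {self.label_cap} outside (0, 1]")
        if self.retention_threshold <= 0.0:
            raise ValueError("retention threshold must be positive")

    def with_options(self, **kwargs) -> "IsotopeConstants":
        """Return a copy with selected fields overridden (e.g. a custom cap)."""
        return replace(self, **kwargs)


CARBON_13 = IsotopeConstants(
    isotope="13C",
    natural_abundance=0.01111233,
    shift_slope=-0.4987282,
    shift_intercept=9.974564,
)

NITROGEN_15 = IsotopeConstants(
    isotope="15N",
    natural_abundance=0.003663,
    shift_slope=0.5024851,
    shift_intercept=3.517396,
)

ISOTOPES = {"13C": CARBON_13, "15N": NITROGEN_15}


def get_isotope(name: str) -> IsotopeConstants:
    try:
        return ISOTOPES[name]
    except KeyError:
        raise KeyError(f"unknown isotope {name!r}; expected one of {sorted(ISOTOPES)}")
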
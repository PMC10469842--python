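"""Forage-fiber C/N bookkeeping for fungal necromass.

Worked-example calculator for the chemical characterisation of low-
and high-melanin fungal necromass by sequential forage-fiber (ANKOM)
analysis: the initial tissue's C and N content, the cell-soluble
fraction removed by neutral detergent, and the non-hydrolyzable
residue left after strong acid. Each fraction is described by the
percent of the initial mass, C, and N it carries, from which its own
C:N ratio follows.

A measured composition table for one low- and one high-melanin
necromass sample ships with the package as the worked example
(``data/necromass_composition.tsv``).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = "necromass_composition.tsv"


def cn_ratio(pct_c: float, pct_n: float) -> float:
    """C:N mass ratio of a tissue, to one decimal."""
    if pct_n <= 0:
        raise ValueError("percent N must be positive")
    if pct_c < 0:
        raise ValueError("percent C must be non-negative")
    return round(pct_c / pct_n, 1)


def fraction_cn(
    init_pct_c: float,
    init_pct_n: float,
    frac_pct_of_init_c: float,
    frac_pct_of_init_n: float,
) -> float:
    """C:N ratio of a fraction from its recoveries of the initial C and N.

    The fraction's C mass is (its % of initial C) x (initial % C), and
    likewise for N; the ratio of the two is the fraction's C:N. It is
    invariant to rescaling both recoveries by a common factor.
    """
    for v, name in [
        (init_pct_c, "initial %C"),
        (init_pct_n, "initial %N"),
        (frac_pct_of_init_c, "fraction % of initial C"),
        (frac_pct_of_init_n, "fraction % of initial N"),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return round((frac_pct_of_init_c * init_pct_c) / (frac_pct_of_init_n * init_pct_n), 1)


def load_composition() -> pd.DataFrame:
    """Packaged necromass composition table (one sample per type)."""
    with resources.files("dualqsip.data").joinpath(_DATA).open() as fh:
        return pd.read_csv(fh, sep="\t")


def composition_report(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute initial and per-fraction C:N ratios from a composition table."""
    df = load_composition() if table is None else table.copy()
    df["initial_cn"] = [cn_ratio(c, n) for c, n in zip(df["pct_c"], df["pct_n"])]
    df["fraction_cn"] = [
        fraction_cn(c, n, fc, fn)
        for c, n, fc, fn in zip(
            df["pct_c"], df["pct_n"], df["pct_initial_c"], df["pct_initial_n"]
        )
    ]
    return df
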
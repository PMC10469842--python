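"""Table readers/writers and run configuration.

File formats
------------
* fraction metadata TSV: ``sample_id, fraction_index, density_g_ml,
  dna_conc_ng_ul`` — densities live here and only here;
* OTU count table: rows are OTU ids, columns keyed
  ``sample_id:fraction_index``; as TSV or as BIOM-style sparse JSON;
* sample manifest TSV: ``sample_id, isotope, necromass_type, stage,
  paired_unlabeled_id`` — every labeled sample points at the unlabeled
  sample of the same necromass type and stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .qsip import FractionRecord

FRACTION_COLUMNS = ["sample_id", "fraction_index", "density_g_ml", "dna_conc_ng_ul"]
MANIFEST_COLUMNS = [
    "sample_id",
    "isotope",
    "necromass_type",
    "stage",
    "paired_unlabeled_id",
]


# ---------------------------------------------------------------------------
# Count tables


def read_counts(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Load an OTU x (sample:fraction) count matrix from TSV or BIOM JSON.

    Format is inferred from the suffix unless given. Counts must be
    non-negative integers and OTU ids unique; violations are reported
    with the offending row and column.
    """
    path = Path(path)
    if format is None:
        format = "biom-json" if path.suffix in {".json", ".biom"} else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "biom-json":
        df = _read_biom_json(path)
    else:
        raise ValueError(f"unknown counts format {format!r}")
    _validate_counts(df, path)
    return df.astype(int)


def _validate_counts(df: pd.DataFrame, path: Path) -> None:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate taxon ids {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = next(zip(*numeric.isna().to_numpy().nonzero()))
        raise ValueError(
            f"{path}: non-numeric count at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if (numeric < 0).any().any():
        r, c = next(zip(*(numeric < 0).to_numpy().nonzero()))
        raise ValueError(
            f"{path}: negative count at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if (numeric != numeric.round()).any().any():
        raise ValueError(f"{path}: non-integer counts")


def write_counts(df: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "biom-json" if path.suffix in {".json", ".biom"} else "tsv"
    if format == "tsv":
        df.to_csv(path, sep="\t", index_label="otu_id")
    elif format == "biom-json":
        _write_biom_json(df, path)
    else:
        raise ValueError(f"unknown counts format {format!r}")


def _read_biom_json(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    df = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            df.iloc[int(i), int(j)] = int(v)
    else:
        for i, row in enumerate(doc["data"]):
            df.iloc[i, :] = [int(v) for v in row]
    return df


def _write_biom_json(df: pd.DataFrame, path: Path) -> None:
    data = [
        [int(i), int(j), int(df.iat[i, j])]
        for i in range(df.shape[0])
        for j in range(df.shape[1])
        if df.iat[i, j] != 0
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "dualqsip",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [int(df.shape[0]), int(df.shape[1])],
        "rows": [{"id": str(r), "metadata": None} for r in df.index],
        "columns": [{"id": str(c), "metadata": None} for c in df.columns],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Fraction metadata and manifest


def read_fractions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FRACTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["dna_conc_ng_ul"] < 0).any():
        raise ValueError(f"{path}: negative DNA concentration")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    validate_manifest(df)
    return df


def validate_manifest(df: pd.DataFrame) -> None:
    """Every labeled sample must pair with an unlabeled sample of the
    same necromass type and stage."""
    by_id = df.set_index("sample_id")
    for _, row in df.iterrows():
        if row["isotope"] == "unlabeled":
            continue
        if row["isotope"] not in {"13C", "15N"}:
            raise ValueError(f"unknown isotope {row['isotope']!r}")
        pid = row["paired_unlabeled_id"]
        if pid not in by_id.index:
            raise ValueError(f"{row['sample_id']}: pair {pid!r} not in manifest")
        pair = by_id.loc[pid]
        if pair["isotope"] != "unlabeled":
            raise ValueError(f"{row['sample_id']}: pair {pid!r} is not unlabeled")
        if (
            pair["necromass_type"] != row["necromass_type"]
            or pair["stage"] != row["stage"]
        ):
            raise ValueError(
                f"{row['sample_id']}: pair {pid!r} differs in necromass type or stage"
            )


# ---------------------------------------------------------------------------
# Records <-> tables


def records_to_tables(
    records: dict[str, list[FractionRecord]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten per-sample fraction records into (counts, fractions) tables."""
    frac_rows = []
    count_cols = {}
    for sample_id, recs in records.items():
        for r in recs:
            frac_rows.append(
                {
                    "sample_id": sample_id,
                    "fraction_index": r.fraction_index,
                    "density_g_ml": r.density,
                    "dna_conc_ng_ul": r.dna_conc,
                }
            )
            count_cols[f"{sample_id}:{r.fraction_index}"] = r.counts
    counts = pd.DataFrame(count_cols).fillna(0).astype(int).sort_index()
    return counts, pd.DataFrame(frac_rows)


def records_from_tables(
    counts: pd.DataFrame, fractions: pd.DataFrame
) -> dict[str, list[FractionRecord]]:
    """Join a count matrix to fraction metadata, keyed ``sample:fraction``.

    Count columns without a metadata row are rejected; metadata rows
    without counts yield empty fractions.
    """
    known = {
        (str(r.sample_id), int(r.fraction_index)): r
        for r in fractions.itertuples()
    }
    for col in counts.columns:
        sample_id, _, idx = str(col).rpartition(":")
        if not sample_id or (sample_id, int(idx)) not in known:
            raise ValueError(f"count column {col!r} has no fraction metadata")
    records: dict[str, list[FractionRecord]] = {}
    for (sample_id, idx), meta in known.items():
        col = f"{sample_id}:{idx}"
        if col in counts.columns:
            series = counts[col]
            taxa_counts = {t: int(c) for t, c in series.items() if c > 0}
        else:
            taxa_counts = {}
        records.setdefault(sample_id, []).append(
            FractionRecord(
                sample_id=sample_id,
                fraction_index=idx,
                density=float(meta.density_g_ml),
                dna_conc=float(meta.dna_conc_ng_ul),
                counts=taxa_counts,
            )
        )
    for recs in records.values():
        recs.sort(key=lambda r: r.fraction_index)
    return records


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Validated settings for a full pipeline run."""

    threshold: float = 0.10
    cap: float = 0.99
    n_boot: int = 1000
    seed: int = 0
    rarefaction_depths: dict = field(
        default_factory=lambda: {"bacteria": 20_000, "fungi": 11_000}
    )
    n_bacteria: int = 200
    n_fungi: int = 100
    reads_per_fraction: int = 20_000

    def __post_init__(self) -> None:
        if not 0.0 < self.cap <= 1.0:
            raise ValueError(f"cap {self.cap} outside (0, 1]")
        if not 0.0 < self.threshold < self.cap:
            raise ValueError(
                f"threshold {self.threshold} must lie in (0, cap={self.cap})"
            )
        if self.n_boot < 0 or self.seed < 0:
            raise ValueError("n_boot and seed must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**doc)
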
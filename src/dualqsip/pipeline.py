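"""End-to-end orchestration: simulate -> AFE estimation -> enrichment stats.

Every stage is deterministic given the root seed in the run
configuration; stage seeds are split from it so that re-running a
single stage reproduces the full run's outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment, io, qsip, synthetic
from .constants import get_isotope

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed split from the root seed (< 2**31)."""
    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_study(config: io.RunConfig, outdir: str | Path) -> synthetic.SyntheticDataset:
    """Generate the synthetic study and write all standard input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = synthetic.GradientDesign(reads_per_fraction=config.reads_per_fraction)
    scenario = synthetic.StudyScenario(
        n_bacteria=config.n_bacteria, n_fungi=config.n_fungi
    )
    ds = synthetic.generate_study(design, scenario, seed=stage_seed(config.seed, "simulate"))
    counts, fractions = io.records_to_tables(ds.records)
    io.write_counts(counts, outdir / "counts.tsv")
    fractions.to_csv(outdir / "fractions.tsv", sep="\t", index=False)
    ds.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    ds.truths.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return ds


def estimate_all_pairs(
    records: dict[str, list[qsip.FractionRecord]],
    manifest: pd.DataFrame,
    threshold: float = 0.10,
    cap: float = 0.99,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AFE estimates for every labeled/unlabeled pair in the manifest.

    Returns a long AFE table (one row per taxon x labeled sample) and
    the pooled skip report.
    """
    afe_frames, skip_frames = [], []
    for row in manifest.itertuples():
        if row.isotope == "unlabeled":
            continue
        k = get_isotope(row.isotope).with_options(
            retention_threshold=threshold, label_cap=cap
        )
        estimates, skips = qsip.estimate_afe_table(
            records[row.sample_id], records[row.paired_unlabeled_id], k
        )
        frame = qsip.afe_table_to_frame(estimates)
        frame.insert(0, "sample_id", row.sample_id)
        frame["necromass_type"] = row.necromass_type
        frame["stage"] = row.stage
        afe_frames.append(frame)
        sf = skips.to_frame()
        sf.insert(0, "sample_id", row.sample_id)
        skip_frames.append(sf)
    afe = pd.concat(afe_frames, ignore_index=True) if afe_frames else pd.DataFrame()
    skip = pd.concat(skip_frames, ignore_index=True) if skip_frames else pd.DataFrame()
    return afe, skip


def enrichment_report(
    afe: pd.DataFrame,
    domains: pd.Series | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Partitions, SMA co-enrichment fits, and community AFE contrasts.

    ``domains`` maps taxon id -> domain label; taxa without a label are
    grouped as ``"all"``. A taxon counts as C- (or N-) enriched when it
    is retained in at least one labeled comparison for that isotope.
    AFE values entering the SMA fit are each taxon's mean normalized
    AFE over the comparisons where it was retained.
    """
    df = afe.copy()
    if domains is not None:
        df["domain"] = df["otu_id"].map(domains).fillna("all")
    else:
        df["domain"] = "all"
    report: dict = {"domains": {}}
    for domain, sub in df.groupby("domain"):
        ret = sub[sub["retained"]]
        sets = {
            iso: frozenset(ret.loc[ret["isotope"] == iso, "otu_id"])
            for iso in ("13C", "15N")
        }
        part = enrichment.EnrichmentPartition(domain, sets["13C"], sets["15N"])
        entry = {
            "partition": part.to_frame().iloc[0].to_dict(),
        }
        co = sets["13C"] & sets["15N"]
        if len(co) >= 3:
            means = (
                ret[ret["otu_id"].isin(co)]
                .groupby(["otu_id", "isotope"])["afe_norm_percent"]
                .mean()
                .unstack()
                / 100.0
            )
            if means["13C"].std() > 0 and means["15N"].std() > 0:
                fit = enrichment.sma_regression(
                    means["13C"].to_numpy(),
                    means["15N"].to_numpy(),
                    n_boot=n_boot,
                    seed=seed,
                )
                entry["sma"] = {
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "x_intercept": fit.x_intercept,
                    "r": fit.r,
                    "n": fit.n,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                }
        for iso in ("13C", "15N"):
            iso_ret = ret[ret["isotope"] == iso]
            if (
                len(iso_ret) >= 4
                and iso_ret["necromass_type"].nunique() == 2
                and iso_ret["stage"].nunique() == 2
            ):
                fit = enrichment.community_afe_model(
                    iso_ret["afe_norm_percent"].to_numpy() / 100.0,
                    iso_ret["necromass_type"],
                    iso_ret["stage"],
                )
                entry[f"model_{iso}"] = {
                    "coef": fit.params.to_dict(),
                    "t": fit.tvalues.to_dict(),
                    "p": fit.pvalues.to_dict(),
                    "adj_r2": fit.rsquared_adj,
                    "direction": fit.direction,
                }
        report["domains"][domain] = entry
    return report


def run_pipeline(
    config: io.RunConfig,
    outdir: str | Path,
    datadir: str | Path | None = None,
) -> dict:
    """Full run: (optionally) simulate, estimate AFE, summarise enrichment.

    Writes the AFE table, skip report, partition/SMA/model summaries and
    a machine-readable ``summary.json`` of all headline numbers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if datadir is None:
        datadir = outdir / "data"
        simulate_study(config, datadir)
    datadir = Path(datadir)

    counts = io.read_counts(datadir / "counts.tsv")
    fractions = io.read_fractions(datadir / "fractions.tsv")
    manifest = io.read_manifest(datadir / "manifest.tsv")
    records = io.records_from_tables(counts, fractions)

    afe, skip = estimate_all_pairs(
        records, manifest, threshold=config.threshold, cap=config.cap
    )
    afe.to_csv(outdir / "afe.tsv", sep="\t", index=False)
    skip.to_csv(outdir / "skip_report.tsv", sep="\t", index=False)

    domains = None
    truth_path = datadir / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        domains = truth.drop_duplicates("taxon_id").set_index("taxon_id")["domain"]

    report = enrichment_report(
        afe, domains, n_boot=config.n_boot, seed=stage_seed(config.seed, "enrich")
    )
    report["n_taxa_estimated"] = int(afe["otu_id"].nunique()) if len(afe) else 0
    report["n_skipped"] = int(len(skip))
    report["config"] = {
        "threshold": config.threshold,
        "cap": config.cap,
        "seed": config.seed,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
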
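"""Readers, writers, rarefaction, and the dataset bundle.

All tables are tab-separated text. A :class:`Bundle` holds the
cross-validated set of inputs the pipeline consumes: sample x genome
abundance, genome x category trait counts, genome metadata, sample
metadata, and optional function metrics / planted truth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Default rarefaction depth (reads per sample) for amplicon count tables.
DEFAULT_RAREFACTION_DEPTH = 5089


@dataclass
class Bundle:
    """A self-consistent dataset: tables cross-referenced by id."""

    abundance: pd.DataFrame          # sample x genome counts or rel. abundances
    trait_counts: pd.DataFrame       # genome x COG category gene counts
    genome_meta: pd.DataFrame        # genome size/quality/taxonomy
    sample_meta: pd.DataFrame        # level/regime/replicate/day per sample
    function_metrics: pd.DataFrame | None = None
    truth: object | None = None      # PlantedTruth when synthetic
    config: object | None = None     # SyntheticConfig when synthetic

    def validate(self) -> "Bundle":
        orphan_genomes = set(self.abundance.columns) - set(self.trait_counts.index)
        if orphan_genomes:
            raise ValueError(
                "abundance genomes missing from trait table: "
                + ", ".join(sorted(map(str, orphan_genomes)))
            )
        orphan_samples = set(self.abundance.index) - set(self.sample_meta.index)
        if orphan_samples:
            raise ValueError(
                "abundance samples missing from metadata: "
                + ", ".join(sorted(map(str, orphan_samples)))
            )
        for name, df in (("abundance", self.abundance),
                         ("trait_counts", self.trait_counts)):
            if df.index.duplicated().any():
                raise ValueError(f"duplicated ids in {name}")
        missing_meta = set(self.trait_counts.index) - set(self.genome_meta.index)
        if missing_meta:
            raise ValueError(
                "trait-table genomes missing from genome metadata: "
                + ", ".join(sorted(map(str, missing_meta)))
            )
        return self


def rarefy(counts: pd.DataFrame, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int = 0) -> pd.DataFrame:
    """Subsample each sample without replacement to exactly ``depth``.

    Samples with total counts below ``depth`` are dropped with a logged
    warning listing their ids. Counts must be integers.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("rarefaction requires integer counts")
        arr = np.round(arr).astype(np.int64)
    rng = np.random.default_rng(seed)
    totals = arr.sum(axis=1)
    keep = totals >= depth
    dropped = counts.index[~keep]
    if len(dropped):
        logger.warning("rarefaction dropped %d samples below depth %d: %s",
                       len(dropped), depth, ", ".join(map(str, dropped)))
    out = np.zeros((int(keep.sum()), arr.shape[1]), dtype=np.int64)
    row_out = 0
    for i in np.flatnonzero(keep):
        row = arr[i]
        if totals[i] == depth:
            out[row_out] = row
        else:
            # multivariate hypergeometric draw = subsampling w/o replacement
            out[row_out] = rng.multivariate_hypergeometric(row, depth)
        row_out += 1
    return pd.DataFrame(out, index=counts.index[keep], columns=counts.columns)


def write_table(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_table(path: Path | str, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_bundle(bundle: Bundle, outdir: Path | str) -> dict[str, Path]:
    """Write all bundle tables (TSV) plus truth table and config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "abundance": bundle.abundance,
        "trait_counts": bundle.trait_counts,
        "genome_meta": bundle.genome_meta,
        "sample_meta": bundle.sample_meta,
    }
    if bundle.function_metrics is not None:
        tables["function_metrics"] = bundle.function_metrics
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        write_table(df, p)
        paths[name] = p
    if bundle.truth is not None:
        p = outdir / "truth.tsv"
        bundle.truth.to_frame().to_csv(p, sep="\t", index=False)
        paths["truth"] = p
    if bundle.config is not None:
        p = outdir / "config.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=True)
        paths["config"] = p
    return paths


def read_inputs(abundance: Path | str, trait_counts: Path | str,
                genome_meta: Path | str, sample_meta: Path | str,
                function_metrics: Path | str | None = None) -> Bundle:
    """Load and cross-validate a bundle from tab-separated files."""
    abundance_table = read_table(abundance)
    # TSV cannot persist the columns-axis name; restore the schema's.
    abundance_table.columns.name = "genome_id"
    bundle = Bundle(
        abundance=abundance_table,
        trait_counts=read_table(trait_counts),
        genome_meta=read_table(genome_meta),
        sample_meta=read_table(sample_meta),
        function_metrics=(read_table(function_metrics)
                          if function_metrics is not None else None),
    )
    return bundle.validate()


def read_bundle_dir(directory: Path | str) -> Bundle:
    """Load a bundle previously written by :func:`write_bundle`."""
    d = Path(directory)
    metrics = d / "function_metrics.tsv"
    return read_inputs(
        d / "abundance.tsv", d / "trait_counts.tsv",
        d / "genome_meta.tsv", d / "sample_meta.tsv",
        metrics if metrics.exists() else None,
    )
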
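"""The normalisation chain that makes count data (RNA-seq) and continuous
intensity data (microarray) comparable:

``raw -> log2(x + pseudocount) -> per-sample background subtraction ->
per-sample mean centering -> per-gene, per-species mean centering``

The per-gene per-species centering is the step that actually enables the
cross-platform join: microarray probe intensities are not comparable
between probes, so every gene is reduced to its deviation from its own
species-wide mean, leaving only temporal shape.  Ops validate the ``scale``
tag so the chain cannot run out of order.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """``log2(x + pseudocount)`` on a raw-scale matrix."""
    if matrix.scale != "raw":
        raise DataError(f"log_transform expects scale 'raw', got {matrix.scale!r}")
    if pseudocount < 0:
        raise ConfigError("pseudocount must be >= 0")
    x = matrix.values.to_numpy(dtype=float)
    if (x < 0).any():
        i, j = np.argwhere(x < 0)[0]
        raise DataError(
            f"negative value at gene {matrix.gene_ids[i]!r}, sample {matrix.sample_ids[j]!r}"
        )
    out = pd.DataFrame(
        np.log2(x + pseudocount), index=matrix.values.index, columns=matrix.values.columns
    )
    return matrix.with_values(out, scale="log")


def background_correct(matrix: ExpressionMatrix, quantile: float = 0.05) -> ExpressionMatrix:
    """Subtract each sample's low-quantile value from that sample.

    A low-quantile location shift aligns platform background floors without
    disturbing within-sample rank order.  The quantile estimator is linear
    interpolation between order statistics (numpy default) so results are
    bit-reproducible.  No clipping: centering follows.
    """
    if matrix.scale != "log":
        raise DataError(f"background_correct expects scale 'log', got {matrix.scale!r}")
    if not 0 < quantile < 1:
        raise ConfigError(f"quantile must be in (0, 1), got {quantile}")
    x = matrix.values.to_numpy(dtype=float)
    floors = np.quantile(x, quantile, axis=0, method="linear")
    return matrix.with_values(
        pd.DataFrame(x - floors, index=matrix.values.index, columns=matrix.values.columns)
    )


def center_samples(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each sample's mean so sample distributions align.  Idempotent."""
    if matrix.scale != "log":
        raise DataError(f"center_samples expects scale 'log', got {matrix.scale!r}")
    x = matrix.values.to_numpy(dtype=float)
    out = x - x.mean(axis=0, keepdims=True)
    return matrix.with_values(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    )


def center_genes_by_species(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center every gene on its own mean within each species independently.

    After this step each gene carries only its temporal deviation per
    species, which is what makes count and intensity platforms jointly
    analysable.  Idempotent; accepts already-centered input.
    """
    if matrix.scale not in ("log", "log_centered"):
        raise DataError(
            f"center_genes_by_species expects scale 'log' or 'log_centered', got {matrix.scale!r}"
        )
    x = matrix.values.to_numpy(dtype=float).copy()
    for species in matrix.species_list():
        cols = (matrix.meta["species"] == species).to_numpy()
        if cols.sum() < 2:
            raise DataError(
                f"species {species!r} has fewer than 2 samples; centering would be degenerate"
            )
        x[:, cols] -= x[:, cols].mean(axis=1, keepdims=True)
    return matrix.with_values(
        pd.DataFrame(x, index=matrix.values.index, columns=matrix.values.columns),
        scale="log_centered",
    )


def average_replicates(matrix: ExpressionMatrix, group_key: str = "replicate_group") -> ExpressionMatrix:
    """Collapse replicate columns to their arithmetic mean, one column per
    group (first-appearance order), metadata taken from each group's first
    member with the group id as the new sample id."""
    if group_key not in matrix.meta.columns:
        raise ConfigError(f"metadata column {group_key!r} not present")
    if (matrix.meta[group_key].astype(str).str.len() == 0).any() or matrix.meta[group_key].isna().any():
        raise DataError(f"empty {group_key!r} value in sample metadata")
    groups = matrix.sample_groups(group_key)
    cols = {}
    meta_rows = []
    for gid, members in groups.items():
        cols[gid] = matrix.values[members].mean(axis=1)
        row = matrix.meta.loc[members[0]].copy()
        row[group_key] = gid
        row.name = gid
        meta_rows.append(row)
    values = pd.DataFrame(cols, index=matrix.values.index)
    meta = pd.DataFrame(meta_rows)
    meta.index.name = "sample_id"
    return ExpressionMatrix(values=values, meta=meta, scale=matrix.scale, species_tag=matrix.species_tag)


#: Canonical step order for the CLI / pipeline.
STEP_FUNCTIONS = {
    "log": log_transform,
    "background": background_correct,
    "center-samples": center_samples,
    "center-genes": center_genes_by_species,
    "average-replicates": average_replicates,
}


def apply_steps(matrix: ExpressionMatrix, steps: list[str], **params) -> ExpressionMatrix:
    """Apply a named subset of the chain in the order given, logging each step.

    Recognised parameters: ``pseudocount`` (log), ``quantile`` (background),
    ``group_key`` (average-replicates).
    """
    for step in steps:
        if step not in STEP_FUNCTIONS:
            raise ConfigError(f"unknown normalisation step {step!r}; options {sorted(STEP_FUNCTIONS)}")
        kwargs = {}
        if step == "log" and "pseudocount" in params:
            kwargs["pseudocount"] = params["pseudocount"]
        if step == "background" and "quantile" in params:
            kwargs["quantile"] = params["quantile"]
        if step == "average-replicates" and "group_key" in params:
            kwargs["group_key"] = params["group_key"]
        log.info("normalisation step %s %s", step, kwargs or "")
        matrix = STEP_FUNCTIONS[step](matrix, **kwargs)
    return matrix
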
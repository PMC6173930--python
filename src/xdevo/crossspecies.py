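"""Two-species integration: ortholog joining, combined PCA with
loading-based gene retrieval, and the phase-averaged conservation screen.

After per-species gene centering, ortholog pairs from the two platforms
can be stacked into one combined matrix.  PCA of that matrix typically
puts developmental age on the first component and residual between-species
variation on the second; genes with large absolute loadings on the
species-separating component are the species-differential candidates.

Temporal conservation is scored per ortholog pair by collapsing each
species' time course to early/intermediate/late phase means and taking the
Pearson correlation of the two 3-point profiles.  With only three points
the null correlation is heavy-tailed (arcsine-like), so the screen is
meaningful only on genes pre-filtered to be differentially expressed in
both species — the ``de_a`` / ``de_b`` masks of
:func:`conservation_screen`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .matrix import ExpressionMatrix, OrthologMap

log = logging.getLogger(__name__)

PHASES = ("early", "intermediate", "late")

#: Canonical phase grouping for an opossum/mouse lung-development
#: comparison: opossum postnatal days 3-14 align with mouse embryonic ages
#: (early), days 29-35 with the early postnatal mouse (intermediate), and
#: day 63/adult with the maturing postnatal mouse (late).
DEFAULT_PHASE_CONFIG: dict[str, dict[str, str]] = {
    "monodelphis": {
        "D3": "early", "D8": "early", "D14": "early",
        "D29": "intermediate", "D35": "intermediate",
        "D63": "late", "ADULT": "late",
    },
    "mouse": {
        "E16": "early", "E18": "early",
        "P2": "intermediate", "P10": "intermediate",
        "P30": "late",
    },
}


# ---------------------------------------------------------------------------
# ortholog joining
# ---------------------------------------------------------------------------
def combine_by_orthologs(
    mat_a: ExpressionMatrix, mat_b: ExpressionMatrix, omap: OrthologMap
) -> ExpressionMatrix:
    """Stack two gene-centered matrices over their shared ortholog pairs.

    Rows are ortholog pairs (identity ``"GENEA|GENEB"``), columns the union
    of both species' samples.  Pairs whose gene is absent from either
    matrix are dropped with a logged count.
    """
    for m, which in ((mat_a, "A"), (mat_b, "B")):
        if m.scale != "log_centered":
            raise DataError(f"matrix {which} must be gene-centered (scale 'log_centered'), got {m.scale!r}")
    if len(omap) == 0:
        raise DataError("ortholog map is empty")
    kept = [
        (a, b)
        for a, b in omap.pairs
        if a in mat_a.values.index and b in mat_b.values.index
    ]
    n_dropped = len(omap) - len(kept)
    if n_dropped:
        log.warning("dropped %d ortholog pair(s) absent from one of the matrices", n_dropped)
    if not kept:
        raise DataError("no ortholog pairs present in both matrices")
    rows_a = mat_a.values.loc[[a for a, _ in kept]].to_numpy()
    rows_b = mat_b.values.loc[[b for _, b in kept]].to_numpy()
    values = pd.DataFrame(
        np.hstack([rows_a, rows_b]),
        index=pd.Index([f"{a}|{b}" for a, b in kept], name="gene_id"),
        columns=mat_a.sample_ids + mat_b.sample_ids,
    )
    meta = pd.concat([mat_a.meta, mat_b.meta])
    return ExpressionMatrix(values=values, meta=meta, scale="log_centered", species_tag="combined")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------
@dataclass
class PCAResult:
    """SVD-based PCA with samples as observations.

    ``loadings`` columns are unit-norm gene weights; the sign convention
    makes each component's largest-magnitude loading positive.  Components
    with negligible singular values (below ``1e-12`` of the largest) are
    dropped, so ``variance_explained`` covers exactly the numerical rank.
    """

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_explained: np.ndarray
    singular_values: np.ndarray


def pca(matrix: ExpressionMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of a gene-centered matrix (no further centering inside)."""
    x = matrix.values.to_numpy(dtype=float).T  # samples x genes
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > 1e-12 * s[0])) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise DataError("matrix has rank 0; nothing to decompose")
    if n_components is not None and n_components > rank:
        log.warning("requested %d components, matrix rank is %d; truncating", n_components, rank)
    k = rank if n_components is None else min(n_components, rank)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(k), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    total = float(np.sum(np.linalg.svd(x, compute_uv=False) ** 2))
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=matrix.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=matrix.values.index, columns=comp_names),
        variance_explained=s**2 / total,
        singular_values=s,
    )


def retrieve_pc_loading_genes(
    result: PCAResult, component: int = 2, threshold: float = 0.04
) -> list[str]:
    """Genes with ``|loading| > threshold`` on a component (1-based),
    sorted by absolute loading, descending.  An unreachable threshold
    yields an empty list (logged), not an error."""
    if not 1 <= component <= result.loadings.shape[1]:
        raise ConfigError(
            f"component {component} unavailable; result has {result.loadings.shape[1]} components"
        )
    lo = result.loadings.iloc[:, component - 1].abs()
    hit = lo[lo > threshold].sort_values(ascending=False, kind="stable")
    if hit.empty:
        log.warning("no gene exceeds |loading| > %s on component %d", threshold, component)
    return list(hit.index)


# ---------------------------------------------------------------------------
# phases & conservation
# ---------------------------------------------------------------------------
def assign_phases(matrix: ExpressionMatrix, mapping: dict[str, dict[str, str]]) -> dict[str, str]:
    """Build a sample -> phase map from an explicit per-species config.

    ``mapping`` is ``{species: {age_label: phase}}``.  Every sample must be
    covered and every species must have at least one sample per phase.
    """
    phases: dict[str, str] = {}
    for sid in matrix.sample_ids:
        species = matrix.meta.loc[sid, "species"]
        age = matrix.meta.loc[sid, "age_label"]
        try:
            phase = mapping[species][age]
        except KeyError:
            raise ConfigError(f"sample {sid!r} (species {species!r}, age {age!r}) has no phase assignment")
        if phase not in PHASES:
            raise ConfigError(f"unknown phase {phase!r} for sample {sid!r}; options {PHASES}")
        phases[sid] = phase
    _validate_phase_cover(matrix, phases)
    return phases


def phases_by_rank(matrix: ExpressionMatrix) -> dict[str, str]:
    """Default phase map: split each species' ordered ages into thirds.

    The earliest third of distinct ages is ``early``, the middle third
    ``intermediate``, the rest ``late`` (remainders go to the earlier
    phase boundary, so every phase is non-empty for >= 3 ages).
    """
    phases: dict[str, str] = {}
    for species in matrix.species_list():
        sub = matrix.meta[matrix.meta["species"] == species]
        ages = sorted(sub["age_order"].unique())
        if len(ages) < 3:
            raise DataError(f"species {species!r} has fewer than 3 distinct ages; cannot form 3 phases")
        cut1 = int(np.ceil(len(ages) / 3))
        cut2 = int(np.ceil(2 * len(ages) / 3))
        for sid, age in sub["age_order"].items():
            rank = ages.index(age)
            phases[sid] = "early" if rank < cut1 else ("intermediate" if rank < cut2 else "late")
    _validate_phase_cover(matrix, phases)
    return phases


def _validate_phase_cover(matrix: ExpressionMatrix, phases: dict[str, str]) -> None:
    for species in matrix.species_list():
        sids = [s for s in matrix.sample_ids if matrix.meta.loc[s, "species"] == species]
        present = {phases[s] for s in sids}
        if set(PHASES) - present:
            raise DataError(
                f"species {species!r} is missing phase(s) {sorted(set(PHASES) - present)}"
            )


def phase_average(matrix: ExpressionMatrix, phases: dict[str, str]) -> dict[str, pd.DataFrame]:
    """Per species, the genes x (early, intermediate, late) mean grid."""
    unassigned = [s for s in matrix.sample_ids if s not in phases]
    if unassigned:
        raise ConfigError(f"samples without phase assignment: {unassigned[:5]}")
    out: dict[str, pd.DataFrame] = {}
    for species in matrix.species_list():
        cols = {}
        for phase in PHASES:
            members = [
                s
                for s in matrix.sample_ids
                if matrix.meta.loc[s, "species"] == species and phases[s] == phase
            ]
            if not members:
                raise DataError(f"species {species!r} has no samples in phase {phase!r}")
            cols[phase] = matrix.values[members].mean(axis=1)
        out[species] = pd.DataFrame(cols)
    return out


def ortholog_profile_correlation(avg_a: pd.DataFrame, avg_b: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of the two 3-point phase profiles per ortholog pair.

    Rows of the two grids must share identity.  Classes at the fixed
    thresholds: ``conserved_strict`` (r > 0.9) subset of ``conserved``
    (r > 0.8); zero-variance profiles are ``undefined`` and excluded from
    conserved counts.
    """
    if list(avg_a.index) != list(avg_b.index):
        raise DataError("phase-average grids must share row identity and order")
    if list(avg_a.columns) != list(PHASES) or list(avg_b.columns) != list(PHASES):
        raise DataError(f"phase-average grids must have columns {PHASES}")
    xa = avg_a.to_numpy(dtype=float)
    xb = avg_b.to_numpy(dtype=float)
    ca = xa - xa.mean(axis=1, keepdims=True)
    cb = xb - xb.mean(axis=1, keepdims=True)
    na = np.sqrt((ca**2).sum(axis=1))
    nb = np.sqrt((cb**2).sum(axis=1))
    ok = (na > 0) & (nb > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.where(ok, (ca * cb).sum(axis=1) / np.where(ok, na * nb, 1.0), np.nan)
    cor = np.clip(cor, -1.0, 1.0)
    cls = np.where(
        ~ok,
        "undefined",
        np.where(cor > 0.9, "conserved_strict", np.where(cor > 0.8, "conserved", "not_conserved")),
    )
    table = pd.DataFrame(
        {
            "a_early": xa[:, 0], "a_intermediate": xa[:, 1], "a_late": xa[:, 2],
            "b_early": xb[:, 0], "b_intermediate": xb[:, 1], "b_late": xb[:, 2],
            "cor": cor,
            "class": cls,
            "conserved": ok & (cor > 0.8),
            "conserved_strict": ok & (cor > 0.9),
        },
        index=avg_a.index,
    )
    return table


def conservation_screen(
    combined: ExpressionMatrix,
    phases: dict[str, str],
    de_a: set[str] | None = None,
    de_b: set[str] | None = None,
) -> pd.DataFrame:
    """Full conservation table for an ortholog-combined matrix.

    When DE gene sets for the two species are supplied, only pairs
    differentially expressed in *both* species are eligible for a
    conserved call (``de_both`` column); the correlation itself is still
    reported for every pair.  ``conserved_call`` is the screen's positive:
    eligible and r > 0.8.
    """
    species = combined.species_list()
    if len(species) != 2:
        raise DataError("conservation screen needs a combined two-species matrix")
    avgs = phase_average(combined, phases)
    table = ortholog_profile_correlation(avgs[species[0]], avgs[species[1]])
    genes_a = [pid.split("|", 1)[0] for pid in table.index]
    genes_b = [pid.split("|", 1)[1] for pid in table.index]
    if de_a is not None and de_b is not None:
        de_both = np.array([a in de_a for a in genes_a]) & np.array([b in de_b for b in genes_b])
    else:
        de_both = np.ones(len(table), dtype=bool)
    table.insert(0, "gene_a", genes_a)
    table.insert(1, "gene_b", genes_b)
    table["de_both"] = de_both
    table["conserved_call"] = de_both & table["conserved"].to_numpy()
    table["conserved_strict_call"] = de_both & table["conserved_strict"].to_numpy()
    return table
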
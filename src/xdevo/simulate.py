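"""Two-species developmental time-course generator with planted structure.

The generator emulates the data layout of a cross-species lung-development
comparison: species A is sampled once per developmental age on a counting
platform (RNA-seq-like, negative-binomial noise around ``2^template`` scaled
by a per-sample library size) and species B is sampled with replicate
animals per age on a continuous-intensity platform (microarray-like,
lognormal noise plus an additive background floor).

Every gene belongs to exactly one planted class:

``conserved_up`` / ``conserved_down`` / ``conserved_peak``
    the same temporal program in both species (time indices aligned by
    rank, i.e. by developmental stage rather than chronological age);
``species_a_late``
    silent until a transition point, then rising — only in species A
    (muscle-like late activation);
``birth_b``
    elevated only in a window at the earliest postnatal ages of species B
    (time-of-birth program);
``flat``
    no temporal program.

The planted labels are returned as a truth table so downstream stages
(differential expression, clustering, the conservation screen, PCA gene
retrieval) can be scored against ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import write_expression_tsv, write_ortholog_map
from .matrix import ExpressionMatrix, OrthologMap

CLASSES = ("conserved_up", "conserved_down", "conserved_peak", "species_a_late", "birth_b", "flat")
CONSERVED_CLASSES = ("conserved_up", "conserved_down", "conserved_peak")

#: Default gene-class mixture: 20% conserved temporal programs, 10%
#: species-A-specific late activation, 5% birth-linked in species B, the
#: rest flat.
DEFAULT_FRACTIONS = {
    "conserved_up": 0.07,
    "conserved_down": 0.07,
    "conserved_peak": 0.06,
    "species_a_late": 0.10,
    "birth_b": 0.05,
    "flat": 0.65,
}


@dataclass
class SimulationConfig:
    """Parameters of the two-species generator.

    Amplitudes and noise are on the log2 scale.  Each platform has one
    noise source: species A's variability (biological + technical) is
    carried entirely by the negative-binomial dispersion of the counting
    platform (variance ``mu + d*mu^2``; at the default ``d = 0.05`` the
    implied log-scale SD, ``sqrt(d)/ln 2 ~ 0.32``, matches the intensity
    platform's ``noise_sd``), while species B's is the lognormal
    ``noise_sd``.  ``background_level`` is the additive intensity floor
    of the continuous platform; ``baseline_range`` is the log2 range of
    per-gene baseline expression (genes below a detection floor are assumed
    filtered upstream).  ``n_prenatal_b`` splits species B's time course
    into prenatal and postnatal ages; the birth window covers the first two
    postnatal ages.
    """

    n_genes: int = 1000
    n_timepoints_a: int = 7
    n_timepoints_b: int = 7
    n_replicates_b: int = 3
    fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    effect_size: float = 2.0
    species_offset_sd: float = 0.5
    noise_sd: float = 0.3
    nb_dispersion: float = 0.05
    background_level: float = 32.0
    baseline_range: tuple[float, float] = (6.0, 12.0)
    library_size_sd: float = 0.2
    ortholog_fraction: float = 0.9
    n_prenatal_b: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_timepoints_a < 2 or self.n_timepoints_b < 2:
            raise ConfigError("each species needs at least 2 time points")
        if self.n_replicates_b < 1:
            raise ConfigError("n_replicates_b must be positive")
        unknown = set(self.fractions) - set(CLASSES)
        if unknown:
            raise ConfigError(f"unknown gene class(es) in fractions: {sorted(unknown)}")
        if any(f < 0 for f in self.fractions.values()):
            raise ConfigError("fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"fractions must sum to 1 (got {total})")
        for name in ("effect_size", "noise_sd", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.species_offset_sd < 0 or self.background_level < 0:
            raise ConfigError("species_offset_sd and background_level must be non-negative")
        if not 0 < self.ortholog_fraction < 1:
            raise ConfigError("ortholog_fraction must be in (0, 1)")
        if not 0 <= self.n_prenatal_b <= self.n_timepoints_b - 2:
            raise ConfigError("n_prenatal_b must leave at least two postnatal time points")

    def class_counts(self) -> dict[str, int]:
        """Gene count per class: ``round(fraction * n_genes)`` with the
        remainder assigned to ``flat``."""
        counts = {c: int(round(self.fractions.get(c, 0.0) * self.n_genes)) for c in CLASSES if c != "flat"}
        n_flat = self.n_genes - sum(counts.values())
        if n_flat < 0:
            raise ConfigError("rounded class counts exceed n_genes")
        counts["flat"] = n_flat
        return counts


def profile_template(
    class_label: str,
    timepoints,
    effect_size: float,
    peak_pos: float = 0.5,
    transition_pos: float = 0.6,
    birth_window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Log2 mean-expression template over ordered developmental ages.

    Ages enter only through their rank: both species are aligned by
    developmental stage, so templates are functions of the normalised rank
    position ``pos = rank / (n - 1)`` in [0, 1].
    """
    timepoints = np.asarray(timepoints, dtype=float)
    n = timepoints.size
    if n < 2:
        raise ConfigError("need at least 2 time points")
    if np.any(np.diff(timepoints) <= 0):
        raise ConfigError("time points must be strictly increasing")
    if effect_size <= 0:
        raise ConfigError("effect_size must be positive")
    pos = np.arange(n) / (n - 1)
    if class_label == "flat":
        return np.zeros(n)
    if class_label == "conserved_up":
        return effect_size * pos
    if class_label == "conserved_down":
        return effect_size * (1.0 - pos)
    if class_label == "conserved_peak":
        if not 0.0 < peak_pos < 1.0:
            raise ConfigError("peak_pos must be strictly interior")
        return effect_size * np.exp(-((pos - peak_pos) ** 2) / (2 * 0.18**2))
    if class_label == "species_a_late":
        if not 0.0 < transition_pos < 1.0:
            raise ConfigError("transition_pos must be strictly interior")
        return effect_size * np.clip((pos - transition_pos) / (1.0 - transition_pos), 0.0, 1.0)
    if class_label == "birth_b":
        if birth_window is None:
            k = max(1, n // 3)
            birth_window = (k, min(k + 1, n - 1))
        out = np.zeros(n)
        lo, hi = birth_window
        if not 0 <= lo <= hi < n:
            raise ConfigError(f"birth_window {birth_window} outside 0..{n - 1}")
        out[lo : hi + 1] = effect_size
        return out
    raise ConfigError(f"unknown gene class {class_label!r}; options {CLASSES}")


def generate_timecourse_pair(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologMap, pd.DataFrame]:
    """Simulate the species pair.

    Returns ``(counts_a, intensities_b, ortholog_map, truth)`` where
    ``truth`` has one row per gene: species-specific gene ids, planted
    class, template parameters, the species offset applied to divergent
    genes in species B, and whether the pair is in the ortholog map.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    counts = cfg.class_counts()
    labels = np.concatenate([[c] * counts[c] for c in CLASSES]).astype(object)

    gene_a = [f"A{i + 1:05d}" for i in range(n)]
    gene_b = [f"B{i + 1:05d}" for i in range(n)]

    lo, hi = cfg.baseline_range
    baseline_a = rng.uniform(lo, hi, size=n)
    baseline_b = rng.uniform(lo, hi, size=n)
    peak_pos = rng.uniform(0.25, 0.75, size=n)
    transition_pos = rng.uniform(0.5, 0.75, size=n)
    divergent = np.isin(labels, ("species_a_late", "birth_b"))
    offsets = np.where(divergent, rng.normal(0.0, cfg.species_offset_sd, size=n), 0.0)

    ages_a = np.arange(1, cfg.n_timepoints_a + 1, dtype=float)
    ages_b = np.arange(1, cfg.n_timepoints_b + 1, dtype=float)
    birth_window = (cfg.n_prenatal_b, cfg.n_prenatal_b + 1)

    tmpl_a = np.zeros((n, cfg.n_timepoints_a))
    tmpl_b = np.zeros((n, cfg.n_timepoints_b))
    for i in range(n):
        c = labels[i]
        kw = dict(peak_pos=peak_pos[i], transition_pos=transition_pos[i])
        if c in CONSERVED_CLASSES:
            tmpl_a[i] = profile_template(c, ages_a, cfg.effect_size, **kw)
            tmpl_b[i] = profile_template(c, ages_b, cfg.effect_size, **kw)
        elif c == "species_a_late":
            tmpl_a[i] = profile_template(c, ages_a, cfg.effect_size, **kw)
        elif c == "birth_b":
            tmpl_b[i] = profile_template(c, ages_b, cfg.effect_size, birth_window=birth_window)
    # baselines are *mean* log2 expression: templates act as zero-mean
    # deviations around them, so a gene's intensity rank carries no
    # information about its temporal class
    tmpl_a -= tmpl_a.mean(axis=1, keepdims=True)
    tmpl_b -= tmpl_b.mean(axis=1, keepdims=True)

    # species A: counting platform, one animal per age.  All of A's noise is
    # carried by the negative binomial: at the default dispersion the
    # log-scale SD (~sqrt(d)/ln 2) is comparable to the intensity
    # platform's noise_sd.
    lib = rng.lognormal(mean=0.0, sigma=cfg.library_size_sd, size=cfg.n_timepoints_a)
    mu = (2.0 ** (baseline_a[:, None] + tmpl_a)) * lib[None, :]
    shape = 1.0 / cfg.nb_dispersion
    values_a = rng.negative_binomial(shape, shape / (shape + mu)).astype(float)
    samples_a = [f"A_T{k + 1}" for k in range(cfg.n_timepoints_a)]
    meta_a = pd.DataFrame(
        {
            "species": "speciesA",
            "age_label": [f"T{k + 1}" for k in range(cfg.n_timepoints_a)],
            "age_order": np.arange(1, cfg.n_timepoints_a + 1),
            "platform": "count",
            "replicate_group": samples_a,
        },
        index=pd.Index(samples_a, name="sample_id"),
    )
    mat_a = ExpressionMatrix(
        values=pd.DataFrame(values_a, index=pd.Index(gene_a, name="gene_id"), columns=samples_a),
        meta=meta_a,
        scale="raw",
        species_tag="speciesA",
    )

    # species B: intensity platform, replicate animals per age
    n_cols_b = cfg.n_timepoints_b * cfg.n_replicates_b
    logmean_b = baseline_b[:, None] + tmpl_b + offsets[:, None]
    logmean_b = np.repeat(logmean_b, cfg.n_replicates_b, axis=1)
    eps_b = rng.normal(0.0, cfg.noise_sd, size=(n, n_cols_b))
    values_b = 2.0 ** (logmean_b + eps_b) + cfg.background_level
    samples_b, labels_b, orders_b, groups_b = [], [], [], []
    for k in range(cfg.n_timepoints_b):
        for r in range(cfg.n_replicates_b):
            samples_b.append(f"B_T{k + 1}_R{r + 1}")
            labels_b.append(f"T{k + 1}")
            orders_b.append(k + 1)
            groups_b.append(f"B_T{k + 1}")
    meta_b = pd.DataFrame(
        {
            "species": "speciesB",
            "age_label": labels_b,
            "age_order": orders_b,
            "platform": "intensity",
            "replicate_group": groups_b,
        },
        index=pd.Index(samples_b, name="sample_id"),
    )
    mat_b = ExpressionMatrix(
        values=pd.DataFrame(values_b, index=pd.Index(gene_b, name="gene_id"), columns=samples_b),
        meta=meta_b,
        scale="raw",
        species_tag="speciesB",
    )

    n_pairs = int(np.floor(cfg.ortholog_fraction * n))
    in_map = np.zeros(n, dtype=bool)
    in_map[np.sort(rng.choice(n, size=n_pairs, replace=False))] = True
    omap = OrthologMap(pairs=[(gene_a[i], gene_b[i]) for i in np.flatnonzero(in_map)])

    truth = pd.DataFrame(
        {
            "gene_a": gene_a,
            "gene_b": gene_b,
            "class": labels,
            "peak_pos": np.where(labels == "conserved_peak", peak_pos, np.nan),
            "transition_pos": np.where(labels == "species_a_late", transition_pos, np.nan),
            "offset": offsets,
            "in_ortholog_map": in_map,
        }
    )
    return mat_a, mat_b, omap, truth


def write_simulation(outdir, mat_a, mat_b, omap, truth: pd.DataFrame) -> None:
    """Write the generator's outputs in the package's standard TSV formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(mat_a, outdir / "a_counts.tsv", outdir / "a_meta.tsv")
    write_expression_tsv(mat_b, outdir / "b_intensity.tsv", outdir / "b_meta.tsv")
    write_ortholog_map(omap, outdir / "orthologs.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
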
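"""Synthetic longitudinal datasets with known ground truth.

Emulates a hormonal-challenge study: ``n`` animals sampled at 4 time points
(0, +1, +4, +24 h) for ~15 plasma/hematology variables with peak-and-recovery
kinetics, plus a probe-level blood transcriptome with duplicated probes per
gene, planted kinetic gene clusters, null genes, between-animal random
intercepts, batch shifts, missing values and outliers.

Every generator returns a *truth record* alongside the data, so that
parameter-recovery tests downstream (differential expression sensitivity,
clustering agreement, mixed-model coefficient recovery) need no re-derivation
of what was planted.

Model
-----
Biological variable ``v`` for animal ``i`` at time ``t``::

    x_itv = (baseline_v + b_iv + g_{batch(i),v}) * fold_tv + shift_tv + e_itv

with ``b_iv ~ N(0, between_sd)`` the animal random intercept, ``g`` the batch
shift, and ``e ~ N(0, noise_sd)`` measurement noise, all on the measurement
scale.  Effects are multiplicative (``fold``, identity 1 at t=0) or additive
(``shift``, 0 at t=0) per variable.

Probe ``p`` of gene ``k`` (on log2 scale)::

    y_pit = mu_k + o_p + delta_k * template_{c(k), t} + u_ik + g_{batch(i)} + e_pit

where ``template_c`` is the kinetic profile of cluster ``c(k)`` (all-zero for
null genes), ``delta_k`` the per-gene effect size in log2 units, ``o_p`` a
fixed probe affinity offset, and ``u_ik`` an animal random intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import DesignError, LongitudinalMatrix

__all__ = [
    "StudyDesign",
    "VariableKinetics",
    "BioKineticsSpec",
    "BioTruth",
    "ExpressionTruth",
    "generate_biological",
    "generate_expression",
    "expression_to_matrix",
    "inject_missing_and_outliers",
    "generate_lmm_dataset",
    "DEFAULT_TIMES",
]

DEFAULT_TIMES = (0, 1, 4, 24)


class ParameterError(ValueError):
    """Raised for invalid generator parameters (negative SDs, rates > 1, ...)."""


# --------------------------------------------------------------------------- #
# Study design
# --------------------------------------------------------------------------- #
@dataclass
class StudyDesign:
    """Balanced repeated-measures design: every animal at every time point.

    Defaults mirror the transcriptome arm of the emulated study: 30 animals,
    4 time points, 2 batches.  The biological arm uses
    :meth:`StudyDesign.biological_default` (120 animals, 3 batches, both
    sexes).
    """

    n_animals: int = 30
    time_points: Sequence[float] = DEFAULT_TIMES
    n_batches: int = 2
    batch_assignment: Mapping[int, int] | None = None
    sex_assignment: Mapping[int, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise DesignError("n_animals must be a positive integer")
        if self.n_batches < 1:
            raise DesignError("n_batches must be a positive integer")
        self.time_points = tuple(self.time_points)
        if len(set(self.time_points)) != len(self.time_points):
            raise DesignError("time points must be distinct")
        if self.batch_assignment is None:
            self.batch_assignment = {i: i % self.n_batches for i in range(self.n_animals)}
        if self.sex_assignment is None:
            self.sex_assignment = {i: "F" for i in range(self.n_animals)}

    @classmethod
    def biological_default(cls, seed: int = 0) -> "StudyDesign":
        """120 animals x 4 times x 3 batches, mixed sexes (63 F / 57 M)."""
        sexes = {i: ("F" if i < 63 else "M") for i in range(120)}
        return cls(n_animals=120, n_batches=3, sex_assignment=sexes, seed=seed)

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    @property
    def n_samples(self) -> int:
        return self.n_animals * self.n_times

    def sample_frame(self) -> pd.DataFrame:
        """One row per sample: animal, time, batch, sex; time fastest-varying."""
        rows = []
        for i in range(self.n_animals):
            for t in self.time_points:
                rows.append(
                    {
                        "sample": f"A{i:03d}_T{_fmt_time(t)}",
                        "animal": i,
                        "time": t,
                        "batch": self.batch_assignment[i],
                        "sex": self.sex_assignment[i],
                    }
                )
        return pd.DataFrame(rows).set_index("sample")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _fmt_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


# --------------------------------------------------------------------------- #
# Biological variables
# --------------------------------------------------------------------------- #
@dataclass
class VariableKinetics:
    """Kinetic profile of a single biological variable on its measurement scale."""

    baseline: float
    noise_sd: float = 0.0
    between_sd: float = 0.0
    batch_sd: float = 0.0
    #: effect per non-baseline time point; 'fold' multiplies, 'shift' adds
    effects: Mapping[float, float] = field(default_factory=dict)
    mode: str = "fold"

    def __post_init__(self) -> None:
        for name in ("noise_sd", "between_sd", "batch_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.mode not in ("fold", "shift"):
            raise ParameterError(f"unknown effect mode {self.mode!r}")

    def effect_at(self, t: float) -> float:
        identity = 1.0 if self.mode == "fold" else 0.0
        if t == 0:
            return identity
        return float(self.effects.get(t, identity))


@dataclass
class BioKineticsSpec:
    """Per-variable kinetics plus missing/outlier contamination rates."""

    variables: Mapping[str, VariableKinetics]
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 5.0  # in units of the column SD

    def __post_init__(self) -> None:
        if not self.variables:
            raise ParameterError("spec must define at least one variable")
        for rate in (self.missing_rate, self.outlier_rate):
            if not 0.0 <= rate <= 1.0:
                raise ParameterError("rates must lie in [0, 1]")

    @classmethod
    def acth_default(cls) -> "BioKineticsSpec":
        """The default challenge scenario: cortisol and FFA peak at +1 h
        (folds 2.7 and 3.21), granulocytes rise while lymphocytes and
        monocytes fall at +1/+4 h, red-cell variables dip, platelets inert.

        Baselines approximate typical piglet reference values on the
        measurement scale; noise SDs are small relative to baselines
        (assay-level variation), between-animal SDs carry the dominant
        inter-individual spread.
        """

        def v(baseline, noise_frac, between_frac, effects, mode="fold"):
            return VariableKinetics(
                baseline=baseline,
                noise_sd=noise_frac * baseline,
                between_sd=between_frac * baseline,
                batch_sd=0.02 * baseline,
                effects=effects,
                mode=mode,
            )

        variables = {
            "cortisol": v(35.0, 0.02, 0.30, {1: 2.70, 4: 0.70, 24: 0.95}),
            "ffa": v(0.16, 0.02, 0.25, {1: 3.21, 4: 1.10, 24: 1.00}),
            "glucose": v(7.7, 0.02, 0.10, {1: 1.02, 4: 1.10, 24: 1.00}),
            "white_cells": v(17.0, 0.02, 0.15, {1: 1.05, 4: 1.05, 24: 1.00}),
            "lymphocytes": v(56.6, 0.02, 0.10, {1: 0.80, 4: 0.75, 24: 1.00}),
            "monocytes": v(7.8, 0.03, 0.12, {1: 0.85, 4: 0.85, 24: 1.00}),
            "granulocytes": v(34.2, 0.02, 0.15, {1: 1.35, 4: 1.45, 24: 1.00}),
            "red_cells": v(5.5, 0.02, 0.08, {1: 1.05, 4: 0.95, 24: 0.93}),
            "mcv": v(53.7, 0.01, 0.07, {}),
            "hematocrit": v(28.7, 0.02, 0.08, {1: 1.05, 4: 0.95, 24: 0.93}),
            "hemoglobin": v(9.75, 0.02, 0.07, {1: 1.05, 4: 0.95, 24: 0.93}),
            "rdw": v(32.6, 0.01, 0.02, {}),
            "platelets": v(410.0, 0.03, 0.15, {}),
            "mpv": v(10.0, 0.02, 0.10, {}),
            "pdw": v(10.8, 0.01, 0.04, {}),
        }
        return cls(variables=variables, missing_rate=0.01, outlier_rate=0.005)


@dataclass
class BioTruth:
    """Everything that was planted in a biological dataset."""

    effects: pd.DataFrame  # variable x time effect actually applied
    modes: pd.Series  # variable -> 'fold' | 'shift'
    intercepts: pd.DataFrame  # animal x variable random intercepts
    batch_shifts: pd.DataFrame  # batch x variable shifts
    missing_mask: pd.DataFrame | None = None
    outlier_mask: pd.DataFrame | None = None


def generate_biological(
    design: StudyDesign,
    spec: BioKineticsSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LongitudinalMatrix, BioTruth]:
    """Generate the biological-variable arm of the synthetic study.

    Missing values and outliers (per ``spec``) are injected last; the truth
    record stores the applied effects, random intercepts, batch shifts and
    contamination masks.
    """
    if spec is None:
        spec = BioKineticsSpec.acth_default()
    if rng is None:
        rng = design.rng()

    frame = design.sample_frame()
    names = list(spec.variables)
    times = design.time_points

    intercepts = pd.DataFrame(
        {
            name: rng.normal(0.0, vk.between_sd, design.n_animals)
            for name, vk in spec.variables.items()
        },
        index=range(design.n_animals),
    )
    batch_shifts = pd.DataFrame(
        {
            name: rng.normal(0.0, vk.batch_sd, design.n_batches)
            for name, vk in spec.variables.items()
        },
        index=range(design.n_batches),
    )

    values = pd.DataFrame(index=frame.index, columns=names, dtype=float)
    for name, vk in spec.variables.items():
        base = (
            vk.baseline
            + intercepts[name].values[frame["animal"].values]
            + batch_shifts[name].values[frame["batch"].values]
        )
        eff = np.array([vk.effect_at(t) for t in frame["time"].values])
        signal = base * eff if vk.mode == "fold" else base + eff
        noise = rng.normal(0.0, vk.noise_sd, len(frame))
        values[name] = signal + noise

    effects = pd.DataFrame(
        {t: [spec.variables[n].effect_at(t) for n in names] for t in times},
        index=names,
    )
    modes = pd.Series({n: spec.variables[n].mode for n in names})

    missing_mask = outlier_mask = None
    if spec.missing_rate > 0 or spec.outlier_rate > 0:
        values, missing_mask, outlier_mask = inject_missing_and_outliers(
            values,
            missing_rate=spec.missing_rate,
            outlier_rate=spec.outlier_rate,
            outlier_magnitude=spec.outlier_magnitude,
            rng=rng,
        )

    matrix = LongitudinalMatrix(
        values=values,
        animal=frame["animal"],
        time=frame["time"],
        batch=frame["batch"],
        sex=frame["sex"],
    )
    truth = BioTruth(
        effects=effects,
        modes=modes,
        intercepts=intercepts,
        batch_shifts=batch_shifts,
        missing_mask=missing_mask,
        outlier_mask=outlier_mask,
    )
    return matrix, truth


# --------------------------------------------------------------------------- #
# Expression
# --------------------------------------------------------------------------- #
#: Kinetic templates over (0, +1, +4, +24) h, in log2 units per unit effect:
#: 1 — sharp peak at +1 h, stable +4 -> +24; 2 — rise to a +4 h peak, decay;
#: 3 — dip at +4 h, back to baseline by +24 h; 4 — net decrease by +24 h.
DEFAULT_TEMPLATES: dict[int, tuple[float, ...]] = {
    1: (0.0, 1.0, 0.30, 0.30),
    2: (0.0, 0.25, 1.0, 0.10),
    3: (0.0, -0.50, -1.0, 0.0),
    4: (0.0, -0.50, -0.25, -1.0),
}

DEFAULT_CLUSTER_SIZES = (18, 17, 8, 22)


@dataclass
class ExpressionTruth:
    """Planted structure of a synthetic probe-level expression dataset."""

    gene_clusters: Mapping[str, int]  # gene -> cluster id, 0 for null genes
    cluster_templates: Mapping[int, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )
    probes_per_gene: int = 3
    effect_size: float = 1.0  # log2 units, scales the templates
    probe_noise_sd: float = 0.2
    probe_offset_sd: float = 0.3
    animal_sd: float = 0.3
    batch_sd: float = 0.1
    baseline_range: tuple[float, float] = (6.0, 12.0)
    n_controls: int = 0

    def __post_init__(self) -> None:
        if self.probes_per_gene < 1:
            raise ParameterError("probes_per_gene must be >= 1")
        for name in ("probe_noise_sd", "probe_offset_sd", "animal_sd", "batch_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        templates = {c: tuple(v) for c, v in self.cluster_templates.items()}
        if len({v for v in templates.values()}) != len(templates):
            raise ParameterError("cluster templates must be distinct vectors")
        self.cluster_templates = templates
        used = {c for c in self.gene_clusters.values() if c != 0}
        missing = used - set(templates)
        if missing:
            raise ParameterError(f"no template for cluster(s) {sorted(missing)}")

    @classmethod
    def default(
        cls,
        cluster_sizes: Sequence[int] = DEFAULT_CLUSTER_SIZES,
        n_null: int = 900,
        **kwargs,
    ) -> "ExpressionTruth":
        """Planted clusters of sizes 18/17/8/22 plus 900 null genes."""
        if any(s < 1 for s in cluster_sizes):
            raise ParameterError("requested cluster sizes must be >= 1")
        genes: dict[str, int] = {}
        for c, size in enumerate(cluster_sizes, start=1):
            for j in range(size):
                genes[f"GC{c}_{j:03d}"] = c
        for j in range(n_null):
            genes[f"NULL_{j:04d}"] = 0
        return cls(gene_clusters=genes, **kwargs)

    @property
    def de_genes(self) -> list[str]:
        return [g for g, c in self.gene_clusters.items() if c != 0]


def generate_expression(
    design: StudyDesign,
    truth: ExpressionTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a probe x sample log2 expression matrix.

    Returns
    -------
    expression : DataFrame, probes in rows, samples in columns
    sample_map : DataFrame (sample -> animal, time, batch)
    probe_map : DataFrame (probe -> gene, is_control, cluster)
    """
    if truth is None:
        truth = ExpressionTruth.default()
    if rng is None:
        rng = design.rng()

    frame = design.sample_frame()
    times = list(design.time_points)
    time_index = {t: j for j, t in enumerate(times)}
    genes = list(truth.gene_clusters)
    n_genes = len(genes)

    baselines = rng.uniform(*truth.baseline_range, n_genes)
    animal_effects = rng.normal(0.0, truth.animal_sd, (design.n_animals, n_genes))
    batch_effects = rng.normal(0.0, truth.batch_sd, (design.n_batches, n_genes))

    t_idx = np.array([time_index[t] for t in frame["time"].values])
    a_idx = frame["animal"].values.astype(int)
    b_idx = frame["batch"].values.astype(int)

    # gene-level signal per sample
    signal = np.empty((n_genes, len(frame)))
    for k, gene in enumerate(genes):
        c = truth.gene_clusters[gene]
        if c == 0:
            profile = np.zeros(len(times))
        else:
            profile = truth.effect_size * np.asarray(truth.cluster_templates[c], dtype=float)
        signal[k] = (
            baselines[k]
            + profile[t_idx]
            + animal_effects[a_idx, k]
            + batch_effects[b_idx, k]
        )

    probe_rows = []
    for k, gene in enumerate(genes):
        for d in range(truth.probes_per_gene):
            probe_rows.append((f"{gene}.p{d}", gene, k, False, truth.gene_clusters[gene]))
    for j in range(truth.n_controls):
        probe_rows.append((f"CTRL_{j:03d}", "", -1, True, 0))

    probe_ids = [r[0] for r in probe_rows]
    offsets = rng.normal(0.0, truth.probe_offset_sd, len(probe_rows))
    data = np.empty((len(probe_rows), len(frame)))
    for p, (probe, gene, k, is_control, _c) in enumerate(probe_rows):
        if is_control:
            # negative controls: low background around 0 on the log2 scale
            data[p] = rng.normal(2.0, 0.3, len(frame))
        else:
            noise = rng.normal(0.0, truth.probe_noise_sd, len(frame))
            data[p] = signal[k] + offsets[p] + noise

    expression = pd.DataFrame(data, index=probe_ids, columns=frame.index)
    sample_map = frame[["animal", "time", "batch"]].copy()
    probe_map = pd.DataFrame(
        {
            "probe": probe_ids,
            "gene": [r[1] for r in probe_rows],
            "is_control": [r[3] for r in probe_rows],
            "cluster": [r[4] for r in probe_rows],
        }
    ).set_index("probe")
    return expression, sample_map, probe_map


def expression_to_matrix(
    expression: pd.DataFrame, sample_map: pd.DataFrame
) -> LongitudinalMatrix:
    """View a probe x sample matrix as a samples x probes LongitudinalMatrix."""
    values = expression.T.loc[sample_map.index]
    return LongitudinalMatrix(
        values=values,
        animal=sample_map["animal"],
        time=sample_map["time"],
        batch=sample_map["batch"],
    )


# --------------------------------------------------------------------------- #
# Contamination
# --------------------------------------------------------------------------- #
def inject_missing_and_outliers(
    values: pd.DataFrame,
    missing_rate: float = 0.0,
    outlier_rate: float = 0.0,
    outlier_magnitude: float = 5.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Replace random cells by NaN and shift others by ``magnitude`` column SDs.

    Each cell is independently made missing with probability ``missing_rate``;
    of the remaining cells, each becomes an outlier with probability
    ``outlier_rate`` (value shifted by +/- ``outlier_magnitude`` column SDs).
    Returns the contaminated copy plus boolean masks of every altered cell.
    """
    for rate in (missing_rate, outlier_rate):
        if not 0.0 <= rate <= 1.0:
            raise ParameterError("rates must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)

    out = values.copy()
    shape = out.shape
    missing = rng.random(shape) < missing_rate
    outlier = (rng.random(shape) < outlier_rate) & ~missing

    if outlier.any():
        col_sd = out.std(axis=0, ddof=1).fillna(1.0).replace(0.0, 1.0).values
        signs = np.where(rng.random(shape) < 0.5, -1.0, 1.0)
        out = out + pd.DataFrame(
            outlier * signs * outlier_magnitude * col_sd,
            index=out.index,
            columns=out.columns,
        )
    out = out.mask(pd.DataFrame(missing, index=out.index, columns=out.columns))

    missing_mask = pd.DataFrame(missing, index=values.index, columns=values.columns)
    outlier_mask = pd.DataFrame(outlier, index=values.index, columns=values.columns)
    return out, missing_mask, outlier_mask


# --------------------------------------------------------------------------- #
# Mixed-model recovery datasets
# --------------------------------------------------------------------------- #
def generate_lmm_dataset(
    design: StudyDesign,
    n_genes: int = 200,
    time_effects: Mapping[float, float] | None = None,
    beta_lg: float = -0.5,
    u_sd: float = 0.3,
    noise_sd: float = 0.2,
    lg_ratio: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Expression generated directly from the cell-composition mixed model
    ``x_it = b0 + b1_t + b2 * (L/G)_it + U_i + e_it``.

    Used by parameter-recovery simulations for the mixed-model stage.  If no
    ``lg_ratio`` is supplied, a lymphocyte/granulocyte ratio trajectory with a
    trough at +1/+4 h (leukocyte redistribution) is simulated.

    Returns (gene x sample expression, L/G ratio per sample, truth table of
    the planted coefficients per gene).
    """
    if rng is None:
        rng = design.rng()
    frame = design.sample_frame()

    if time_effects is None:
        time_effects = {1: 1.0, 4: 0.5, 24: -0.25}

    if lg_ratio is None:
        lg_base = {0: 1.65, 1: 0.95, 4: 0.85, 24: 1.60}
        lg_animal = rng.normal(0.0, 0.25, design.n_animals)
        lg = np.array(
            [
                max(lg_base.get(t, 1.5) + lg_animal[int(a)] + rng.normal(0.0, 0.12), 0.05)
                for a, t in zip(frame["animal"], frame["time"])
            ]
        )
        lg_ratio = pd.Series(lg, index=frame.index, name="lg_ratio")
    else:
        lg_ratio = pd.Series(np.asarray(lg_ratio), index=frame.index, name="lg_ratio")

    t_eff = np.array([0.0 if t == 0 else time_effects.get(t, 0.0) for t in frame["time"]])
    a_idx = frame["animal"].values.astype(int)

    data = np.empty((n_genes, len(frame)))
    b0 = rng.uniform(6.0, 12.0, n_genes)
    for k in range(n_genes):
        u = rng.normal(0.0, u_sd, design.n_animals)
        data[k] = (
            b0[k]
            + t_eff
            + beta_lg * lg_ratio.values
            + u[a_idx]
            + rng.normal(0.0, noise_sd, len(frame))
        )

    genes = [f"LMM_{k:03d}" for k in range(n_genes)]
    expression = pd.DataFrame(data, index=genes, columns=frame.index)
    truth = pd.DataFrame(
        {
            "beta0": b0,
            "beta_lg": beta_lg,
            **{f"beta_t{_fmt_time(t)}": e for t, e in time_effects.items()},
        },
        index=genes,
    )
    return expression, lg_ratio, truth
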
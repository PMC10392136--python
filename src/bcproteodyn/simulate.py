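"""Synthetic cohorts and perturbation time courses with planted ground truth.

The generator emulates the structure of a DIA proteotyping study of a
breast-cancer cell-line panel:

* a multi-omics cohort — transcript, protein and binary mutation layers over
  ~76 cell lines (39 TNBC), with 3 biological + 1 technical replicate columns
  per line in the protein layer, a mild additive batch shift in replicate
  group 4, protein–mRNA coupling with a target median Pearson r, one shared
  latent factor per protein complex driving subunit co-expression,
  abundance-dependent (logistic, missing-not-at-random) missingness tuned to
  a target overall rate, and drug responses that depend sparsely and linearly
  on planted predictor proteins;
* a perturbation time course — 9 lines (5 TNBC) x 3 drugs x 6 time points
  {0,4,12,24,48,72} h x 3 replicates, with planted monotone trends (log2
  expression linear in time, reaching baseline x FC at 72 h), a planted set
  whose trend direction is opposite between TNBC and non-TNBC lines, planted
  transient responders that return to baseline, and proteins whose expression
  tracks each line's log10 IC50 at every time point.

Every planted signal is recorded in :class:`PlantedTruth`, so downstream
analyses can be scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ComplexCatalog,
    DrugResponseTable,
    OmicsMatrix,
    SampleAnnotation,
    TimeCourseExperiment,
    TIME_POINTS_H,
)

__all__ = [
    "CohortSimSpec",
    "TimeCourseSimSpec",
    "PlantedTruth",
    "generate_cohort",
    "generate_timecourse",
]


@dataclass
class CohortSimSpec:
    """Study-design parameters of the simulated cell-line cohort.

    Dimensions default to the published study (76 lines of which 39 TNBC,
    6091 proteins, 29,140 transcripts, 123 mutations, 90 drugs, 34.7 %
    overall protein missingness, median protein–mRNA r of 0.3).
    """

    n_cell_lines: int = 76
    n_tnbc: int = 39
    n_proteins: int = 6091
    n_transcripts: int = 29140
    n_mutations: int = 123
    n_drugs: int = 90
    target_missing_fraction: float = 0.347
    r_target: float = 0.3                 # median feature-wise protein-mRNA r
    n_complexes: int = 622
    complex_size_range: tuple[int, int] = (2, 6)
    complex_strength: float = 1.0         # sd of the shared per-complex factor
    n_predictors_per_drug: int = 5
    predictor_beta: float = 1.0
    response_noise_sd: float = 0.5
    n_tnbc_de: int = 100                  # proteins shifted between subgroups
    tnbc_de_log2fc: float = 1.0           # magnitude of the planted shift
    baseline_mean: float = 20.0           # log2 abundance scale
    baseline_sd: float = 2.0
    line_sd: float = 1.0                  # between-line biological signal
    bio_sd: float = 0.25                  # biological replicate noise (log2)
    tech_sd: float = 0.10                 # extra technical replicate noise
    batch_offset: float = 0.3             # additive shift for replicate group 4
    missing_slope: float = 1.5            # logistic width of the missing model
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.target_missing_fraction < 1:
            raise ValueError("target_missing_fraction must be in [0, 1)")
        if self.n_tnbc > self.n_cell_lines:
            raise ValueError("n_tnbc cannot exceed n_cell_lines")
        if self.tech_sd > self.bio_sd:
            raise ValueError("technical noise sd must be <= biological noise sd")
        if self.r_target >= 1:
            raise ValueError("infeasible protein-mRNA coupling: r_target >= 1")


@dataclass
class TimeCourseSimSpec:
    """Design of the simulated drug-perturbation proteome."""

    n_lines: int = 9
    n_tnbc: int = 5
    n_drugs: int = 3
    n_proteins: int = 5621
    time_points_h: tuple[float, ...] = TIME_POINTS_H
    n_replicates: int = 3
    n_monotone_per_drug: int = 40
    monotone_fc: float = 4.0              # last-vs-first linear fold change
    n_opposite: int = 30
    opposite_fc: float = 4.0
    n_transient: int = 20                 # respond early, back to baseline by 72 h
    transient_shift: float = 2.0          # peak log2 shift
    n_ic50_tracking: int = 20
    ic50_r_target: float = 0.8
    noise_sd: float = 0.2                 # replicate noise, log2
    line_sd: float = 0.5                  # per-(protein, line) baseline offset
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    target_missing_fraction: float = 0.336
    missing_slope: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.target_missing_fraction < 1:
            raise ValueError("target_missing_fraction must be in [0, 1)")
        if self.n_tnbc > self.n_lines:
            raise ValueError("n_tnbc cannot exceed n_lines")
        for fc in (self.monotone_fc, self.opposite_fc):
            if fc <= 0:
                raise ValueError("fold changes must be > 0")
        if not 0 <= self.ic50_r_target < 1:
            raise ValueError("ic50_r_target must be in [0, 1)")
        planted = (self.n_monotone_per_drug * self.n_drugs + self.n_opposite
                   + self.n_transient + self.n_ic50_tracking * self.n_drugs)
        if planted > int(0.6 * self.n_proteins):
            raise ValueError(
                "planted sets exceed the upper-abundance pool "
                f"({planted} > {int(0.6 * self.n_proteins)}); "
                "increase n_proteins or shrink the planted sets"
            )


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset (the test oracle)."""

    predictors: dict[str, dict[str, float]] = field(default_factory=dict)
    complex_catalog: ComplexCatalog | None = None
    tnbc_de: dict[str, float] = field(default_factory=dict)
    realized_missing_fraction: float = 0.0
    monotone: dict[str, dict[str, float]] = field(default_factory=dict)
    opposite: dict[str, int] = field(default_factory=dict)   # protein -> TNBC sign
    transient: list[str] = field(default_factory=list)
    ic50_tracking: dict[str, dict[str, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def _abundance_missing_mask(values: np.ndarray, target: float, slope: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Missing-not-at-random mask: P(missing) is logistic, decreasing in log2
    abundance, with the intercept solved (bisection) so the expected overall
    missing fraction equals ``target``."""
    if target <= 0:
        return np.zeros(values.shape, dtype=bool)
    flat = values.ravel()

    def expected(x0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp((flat - x0) / slope))))

    lo, hi = flat.min() - 20 * slope, flat.max() + 20 * slope
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    p_miss = 1.0 / (1.0 + np.exp((values - 0.5 * (lo + hi)) / slope))
    return rng.random(values.shape) < p_miss


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _line_names(n: int) -> list[str]:
    return [f"CL{i + 1:03d}" for i in range(n)]


def generate_cohort(spec: CohortSimSpec):
    """Simulate the multi-omics cohort.

    Returns
    -------
    matrices : dict with layers ``"M"`` (mutation), ``"E"`` (transcript) and
        ``"D"`` (protein, replicate-level, 4 columns per line).  ``E`` and
        ``M`` are cell-line-level (one column per line, keyed by cell line);
        ``D`` columns are opaque sample ids joined via the annotation.
    annotation : SampleAnnotation for the replicate-level protein samples.
    response : DrugResponseTable (log10 IC50-like scale).
    truth : PlantedTruth with per-drug predictors, the complex catalog and
        the realized missing fraction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lines = _line_names(spec.n_cell_lines)
    tnbc = np.array([i < spec.n_tnbc for i in range(spec.n_cell_lines)])
    subtype = np.where(
        tnbc,
        np.where(np.arange(spec.n_cell_lines) % 2 == 0, "basal_a", "basal_b"),
        np.where(np.arange(spec.n_cell_lines) % 2 == 0, "luminal", "her2"),
    )

    # transcript layer: per-feature log-normal baseline + between-line signal.
    # Protein j and transcript j measure the same gene and share its id, so
    # complex catalogs map onto both layers.
    t_ids = [f"G{i + 1:05d}" for i in range(spec.n_transcripts)]
    p_ids = [f"G{i + 1:05d}" for i in range(spec.n_proteins)]
    mu_t = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_transcripts)
    z = rng.standard_normal((spec.n_transcripts, spec.n_cell_lines))
    transcripts = mu_t[:, None] + spec.line_sd * z

    # protein complexes: disjoint member sets, one shared latent factor each
    sizes = rng.integers(spec.complex_size_range[0],
                         spec.complex_size_range[1] + 1, spec.n_complexes)
    pool = rng.permutation(spec.n_proteins)
    catalog, cursor, complex_of = {}, 0, np.full(spec.n_proteins, -1)
    for ci, size in enumerate(sizes):
        if cursor + size > spec.n_proteins:
            break
        members = pool[cursor:cursor + size]
        cursor += size
        catalog[f"CPX{ci + 1:04d}"] = frozenset(p_ids[j] for j in members)
        complex_of[members] = ci

    # protein layer: couple protein j to transcript j.  Coupling loadings are
    # scaled per feature so the protein-mRNA correlation equals r_target for
    # complex members too (whose shared factor otherwise dilutes it):
    # corr = a / sqrt(a^2 + c^2 + e^2) with e^2 = 1 - r^2 fixed, solved for a.
    mu_p = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_proteins)
    r = spec.r_target
    resid_var = 1.0 - r * r
    n_cpx = int(complex_of.max()) + 1
    in_cpx = complex_of >= 0
    c2 = np.where(in_cpx, spec.complex_strength ** 2, 0.0)
    a = np.sqrt(r * r / (1 - r * r) * (c2 + resid_var))
    n_coupled = min(spec.n_proteins, spec.n_transcripts)
    signal = np.zeros((spec.n_proteins, spec.n_cell_lines))
    signal[:n_coupled] = a[:n_coupled, None] * z[:n_coupled]
    signal += math.sqrt(resid_var) * rng.standard_normal(signal.shape)
    if n_cpx > 0:
        factors = rng.standard_normal((n_cpx, spec.n_cell_lines))
        signal[in_cpx] += spec.complex_strength * factors[complex_of[in_cpx]]
    protein_line = mu_p[:, None] + spec.line_sd * signal

    # planted TNBC-vs-rest differential proteins (random sign per feature)
    tnbc_de: dict[str, float] = {}
    if spec.n_tnbc_de > 0:
        de_idx = rng.choice(spec.n_proteins, min(spec.n_tnbc_de,
                                                 spec.n_proteins),
                            replace=False)
        de_sign = rng.choice([-1.0, 1.0], len(de_idx))
        protein_line[np.ix_(de_idx, np.where(tnbc)[0])] += (
            de_sign[:, None] * spec.tnbc_de_log2fc)
        tnbc_de = {p_ids[j]: float(s * spec.tnbc_de_log2fc)
                   for j, s in zip(de_idx, de_sign)}

    # mutation layer (per cell line, binary, complete)
    m_ids = [f"MUT{i + 1:04d}" for i in range(spec.n_mutations)]
    m_rates = rng.uniform(0.02, 0.30, spec.n_mutations)
    mutations = (rng.random((spec.n_mutations, spec.n_cell_lines))
                 < m_rates[:, None]).astype(float)

    # drug responses: sparse linear in standardized true protein line values
    drugs = [f"DRUG{i + 1:03d}" for i in range(spec.n_drugs)]
    p_std = (protein_line - protein_line.mean(axis=1, keepdims=True))
    sd = protein_line.std(axis=1, keepdims=True)
    p_std = np.divide(p_std, sd, out=np.zeros_like(p_std), where=sd > 0)
    response = np.empty((spec.n_cell_lines, spec.n_drugs))
    predictors: dict[str, dict[str, float]] = {}
    for di, drug in enumerate(drugs):
        chosen = rng.choice(spec.n_proteins, spec.n_predictors_per_drug,
                            replace=False)
        betas = spec.predictor_beta * rng.choice([-1.0, 1.0],
                                                 spec.n_predictors_per_drug)
        predictors[drug] = {p_ids[j]: float(b) for j, b in zip(chosen, betas)}
        y = p_std[chosen].T @ betas
        y = y + rng.normal(0.0, spec.response_noise_sd, spec.n_cell_lines)
        response[:, di] = y + rng.normal(-6.0, 1.0)   # log10 IC50-like offset

    # replicate-level protein matrix: groups 1-3 biological, group 4 = extra
    # technical noise on top of group 3 plus the instrument batch shift
    sample_ids, col_line, col_group = [], [], []
    for li, line in enumerate(lines):
        for g in range(1, 5):
            sample_ids.append(f"{line}_r{g}")
            col_line.append(li)
            col_group.append(g)
    col_line = np.array(col_line)
    col_group = np.array(col_group)
    bio = rng.normal(0.0, spec.bio_sd, (spec.n_proteins, spec.n_cell_lines, 3))
    data = np.empty((spec.n_proteins, len(sample_ids)))
    for ci, (li, g) in enumerate(zip(col_line, col_group)):
        base = protein_line[:, li] + bio[:, li, min(g, 3) - 1]
        if g == 4:
            base = (base + rng.normal(0.0, spec.tech_sd, spec.n_proteins)
                    + spec.batch_offset)
        data[:, ci] = base

    mask = _abundance_missing_mask(data, spec.target_missing_fraction,
                                   spec.missing_slope, rng)
    data[mask] = np.nan
    realized = float(mask.mean())

    ann = SampleAnnotation(pd.DataFrame(
        {
            "cell_line": [lines[li] for li in col_line],
            "subtype": [subtype[li] for li in col_line],
            "tnbc": [bool(tnbc[li]) for li in col_line],
            "replicate_group": col_group,
            "replicate_type": ["technical" if g == 4 else "biological"
                               for g in col_group],
            "batch": ["B2" if g == 4 else "B1" for g in col_group],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    matrices = {
        "M": OmicsMatrix("mutation", pd.DataFrame(mutations, index=m_ids,
                                                  columns=lines)),
        "E": OmicsMatrix("transcript", pd.DataFrame(transcripts, index=t_ids,
                                                    columns=lines)),
        "D": OmicsMatrix("protein", pd.DataFrame(data, index=p_ids,
                                                 columns=sample_ids)),
    }
    truth = PlantedTruth(
        predictors=predictors,
        complex_catalog=ComplexCatalog(catalog),
        tnbc_de=tnbc_de,
        realized_missing_fraction=realized,
    )
    resp = DrugResponseTable(pd.DataFrame(response, index=lines, columns=drugs))
    return matrices, ann, resp, truth


# ---------------------------------------------------------------------------
# perturbation time course
# ---------------------------------------------------------------------------

def generate_timecourse(spec: TimeCourseSimSpec):
    """Simulate the perturbation proteome.

    Planted signal classes (disjoint, drawn from the upper 60 % of the
    baseline-abundance range so that drug-responsive proteins are well
    quantified, as any selected protein in a real experiment must be):

    * ``monotone`` (per drug): log2 expression moves linearly in time from the
      baseline to baseline + sign * log2(FC) at 72 h, in every line;
    * ``opposite``: same ramp under every drug but with the sign flipped
      between TNBC and non-TNBC lines;
    * ``transient``: shifted over 4-24 h, back to baseline at 48-72 h;
    * ``ic50_tracking`` (per drug): expression offset proportional to the
      line's standardized log10 IC50 at every time point, with the slope set
      so the expected per-time-point Pearson r across lines equals
      ``ic50_r_target`` given the replicate noise (exactly 1 when noiseless).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lines = _line_names(spec.n_lines)
    tnbc = {line: i < spec.n_tnbc for i, line in enumerate(lines)}
    drugs = [f"DRUG{i + 1:02d}" for i in range(spec.n_drugs)]
    times = np.array(spec.time_points_h, dtype=float)
    p_ids = [f"P{i + 1:05d}" for i in range(spec.n_proteins)]

    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_proteins)
    # planted proteins drawn from the upper-abundance features
    order = np.argsort(mu)
    high = order[int(0.4 * spec.n_proteins):]
    n_planted = (spec.n_monotone_per_drug * spec.n_drugs + spec.n_opposite
                 + spec.n_transient + spec.n_ic50_tracking * spec.n_drugs)
    planted = rng.choice(high, size=n_planted, replace=False)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = planted[cursor:cursor + n]
        cursor += n
        return out

    monotone_idx = {d: take(spec.n_monotone_per_drug) for d in drugs}
    opposite_idx = take(spec.n_opposite)
    transient_idx = take(spec.n_transient)
    tracking_idx = {d: take(spec.n_ic50_tracking) for d in drugs}

    monotone_sign = {d: rng.choice([-1, 1], spec.n_monotone_per_drug)
                     for d in drugs}
    opposite_sign = rng.choice([-1, 1], spec.n_opposite)  # sign in TNBC lines
    transient_sign = rng.choice([-1, 1], spec.n_transient)
    tracking_sign = {d: rng.choice([-1, 1], spec.n_ic50_tracking) for d in drugs}

    # drug response table for the 9 lines
    ic50 = rng.normal(-6.0, 1.0, (spec.n_lines, spec.n_drugs))
    resp = DrugResponseTable(pd.DataFrame(ic50, index=lines, columns=drugs))
    ic50_z = (ic50 - ic50.mean(axis=0)) / ic50.std(axis=0)

    # slope giving the target cross-line correlation for replicate-mean profiles
    r = spec.ic50_r_target
    noise_var = spec.noise_sd ** 2 / spec.n_replicates
    if r <= 0:
        gamma = 0.0
    elif noise_var == 0:
        gamma = 0.5          # noiseless: any non-zero slope gives r = 1
    else:
        gamma = math.sqrt(r * r / (1 - r * r) * noise_var)

    ramp = times / times[-1]                         # 0 -> 1 over the course
    transient_bump = np.interp(times, [0, 4, 24, 48, 72], [0, 1, 1, 0, 0])

    # per-(protein, line) baseline offsets; IC50 trackers get none so their
    # cross-line variation is exactly slope * IC50 + noise
    line_offset = rng.normal(0.0, spec.line_sd,
                             (spec.n_proteins, spec.n_lines))
    for d in drugs:
        line_offset[tracking_idx[d]] = 0.0

    cols = pd.MultiIndex.from_product(
        [lines, drugs, times, range(1, spec.n_replicates + 1)],
        names=["cell_line", "drug", "time_h", "replicate"],
    )
    data = np.empty((spec.n_proteins, len(cols)))
    tnbc_arr = np.array([tnbc[l] for l in lines])

    for li, line in enumerate(lines):
        for di, drug in enumerate(drugs):
            profile = np.tile((mu + line_offset[:, li])[:, None], (1, len(times)))
            idx = monotone_idx[drug]
            profile[idx] += (monotone_sign[drug][:, None]
                             * math.log2(spec.monotone_fc) * ramp[None, :])
            osign = np.where(tnbc_arr[li], opposite_sign, -opposite_sign)
            profile[opposite_idx] += (osign[:, None]
                                      * math.log2(spec.opposite_fc)
                                      * ramp[None, :])
            profile[transient_idx] += (transient_sign[:, None]
                                       * spec.transient_shift
                                       * transient_bump[None, :])
            tidx = tracking_idx[drug]
            profile[tidx] += (tracking_sign[drug][:, None]
                              * gamma * ic50_z[li, di])
            for rep in range(spec.n_replicates):
                noise = (rng.normal(0.0, spec.noise_sd,
                                    (spec.n_proteins, len(times)))
                         if spec.noise_sd > 0 else 0.0)
                start = (((li * spec.n_drugs) + di) * len(times)
                         * spec.n_replicates)
                sel = slice(start + rep, start + len(times) * spec.n_replicates,
                            spec.n_replicates)
                data[:, sel] = profile + noise

    # detectability is feature-level: P(missing) logistic in the protein's
    # baseline abundance (DIA drop-out tracks a protein's peptide properties
    # more than its modest within-course abundance changes)
    mask = _abundance_missing_mask(
        np.broadcast_to(mu[:, None], data.shape),
        spec.target_missing_fraction, spec.missing_slope, rng)
    data[mask] = np.nan

    tc = TimeCourseExperiment(pd.DataFrame(data, index=p_ids, columns=cols),
                              tnbc)
    truth = PlantedTruth(
        realized_missing_fraction=float(mask.mean()),
        monotone={d: {p_ids[j]: float(spec.monotone_fc ** s)
                      for j, s in zip(monotone_idx[d], monotone_sign[d])}
                  for d in drugs},
        opposite={p_ids[j]: int(s)
                  for j, s in zip(opposite_idx, opposite_sign)},
        transient=[p_ids[j] for j in transient_idx],
        ic50_tracking={d: {p_ids[j]: int(s)
                           for j, s in zip(tracking_idx[d], tracking_sign[d])}
                       for d in drugs},
    )
    return tc, resp, truth
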
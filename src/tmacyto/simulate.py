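"""Synthetic TMA cohort generator.

Emulates the statistical and spatial structure the downstream analysis
assumes, so every stage is testable without patient data:

* circular cores (default 1.5 mm diameter) with phenotype counts drawn
  Poisson from per-phenotype densities and positions uniform on the disc;
* per-marker intensities as two-component log-normal mixtures (positive
  population brighter than negative), DAPI positive for every cell;
* spatial attraction of PD-1+CD8+ T cells to PD-L1+CD68+ macrophages as a
  parent–offspring (Thomas-like) displacement: a fraction kappa/(1+kappa) of
  the PD-1+CD8+ cells is re-placed at Gaussian offsets (sd sigma) from
  randomly chosen PD-L1+CD68+ cells, rejection-resampled to stay inside the
  disc.  kappa = 0 leaves the pattern completely spatially random;
* per-patient PD-1+|CD8+ and PD-L1+|CD68+ fractions drawn from a correlated
  bivariate normal on the logit scale (correlation rho), so the two subset
  proportions covary across patients;
* censored survival from an exponential proportional-hazards model whose
  linear predictor uses the patient's TRUE proportions, so Cox fits are
  correctly specified for parameter-recovery tests.

Every operation takes a seed or :class:`numpy.random.Generator`; per-sample
substreams are spawned from a single SeedSequence so cohorts are fully
reproducible and adding a sample does not perturb the others' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import CellTable
from .markers import MARKER_NAMES

GENERATOR_PHENOTYPES = ("tumor", "helper_t", "cytotoxic_t", "treg", "macrophage", "other")

#: True lineage-marker positivity for each generator phenotype (DAPI always true).
_LINEAGE_MARKERS: dict[str, tuple[str, ...]] = {
    "tumor": ("tumor_marker",),
    "helper_t": ("cd3",),
    "cytotoxic_t": ("cd3", "cd8"),
    "treg": ("cd3", "foxp3"),
    "macrophage": ("cd68",),
    "other": (),
}


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerMixture:
    """Log-normal intensity mixture for one marker (log a.u.)."""

    neg_log_mean: float
    neg_log_sd: float
    pos_log_mean: float
    pos_log_sd: float

    def __post_init__(self):
        if self.pos_log_mean <= self.neg_log_mean:
            raise ParameterError("positive population must be brighter than negative")


@dataclass(frozen=True)
class IntensityModel:
    """Per-marker two-component log-normal intensity mixtures."""

    mixtures: dict[str, MarkerMixture]

    def __post_init__(self):
        missing = set(MARKER_NAMES) - set(self.mixtures)
        if missing:
            raise ParameterError(f"intensity model missing markers: {sorted(missing)}")

    @classmethod
    def default(cls, separation: float = 20.0, neg_log_mean: float = 2.0,
                log_sd: float = 0.5) -> "IntensityModel":
        """Homogeneous panel: positive mean = ``separation`` x negative mean."""
        mix = MarkerMixture(neg_log_mean, log_sd, neg_log_mean + math.log(separation), log_sd)
        return cls({m: mix for m in MARKER_NAMES})


@dataclass(frozen=True)
class CompositionParams:
    """Expected phenotype densities (cells/mm^2) and functional fractions."""

    densities: dict[str, float]
    p_pd1_given_cd8: float = 0.35
    p_pdl1_given_cd68: float = 0.35
    p_pdl1_given_tumor: float = 0.30

    def __post_init__(self):
        unknown = set(self.densities) - set(GENERATOR_PHENOTYPES)
        if unknown:
            raise ParameterError(f"unknown phenotypes: {sorted(unknown)}")
        if any(d < 0 for d in self.densities.values()):
            raise ParameterError("densities must be >= 0")
        for p in (self.p_pd1_given_cd8, self.p_pdl1_given_cd68, self.p_pdl1_given_tumor):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("functional fractions must be in [0, 1]")


@dataclass(frozen=True)
class AttractionParams:
    """Thomas-like attraction of PD-1+CD8+ cells toward PD-L1+CD68+ cells.

    ``kappa`` (dimensionless, >= 0): a fraction kappa/(1+kappa) of PD-1+CD8+
    cells is placed near references; 0 means complete spatial randomness.
    ``sigma_um``: dispersion (µm) of the Gaussian placement around a reference.
    """

    kappa: float = 0.0
    sigma_um: float = 15.0

    def __post_init__(self):
        if self.kappa < 0 or self.sigma_um <= 0:
            raise ParameterError("kappa must be >= 0 and sigma_um > 0")

    @property
    def attracted_fraction(self) -> float:
        return self.kappa / (1.0 + self.kappa)


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential proportional-hazards generator.

    Hazard = baseline_rate * exp(sum_j beta_j * (z_j - ref_j)) with covariates
    z = (prop PD-1+CD8+ of CD8+, prop PD-L1+CD68+ of CD68+, age, sex_male,
    stage).  Censoring is an independent exponential clock plus administrative
    cut-off at ``max_followup`` months.
    """

    baseline_rate: float = 0.035          # events/month at reference covariates
    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "prop_pd1_cd8": 1.6,
            "prop_pdl1_cd68": 1.0,
            "age": 0.02,
            "sex_male": 0.1,
            "stage": 0.35,
        }
    )
    reference: dict[str, float] = field(
        default_factory=lambda: {
            "prop_pd1_cd8": 0.35,
            "prop_pdl1_cd68": 0.35,
            "age": 63.0,
            "sex_male": 0.5,
            "stage": 2.0,
        }
    )
    censoring_rate: float = 0.03          # events/month, independent of survival
    max_followup: float = 72.0            # months

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ParameterError("baseline_rate must be > 0")

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        lp = np.zeros(len(covariates))
        for name, beta in self.coefficients.items():
            lp += beta * (covariates[name].to_numpy(dtype=float) - self.reference.get(name, 0.0))
        return lp


# ---------------------------------------------------------------------------
# default compositions (PDAC-like tumor and adjacent-normal cores)

TUMOR_DENSITIES = {
    "tumor": 400.0, "helper_t": 45.0, "cytotoxic_t": 40.0,
    "treg": 18.0, "macrophage": 80.0, "other": 150.0,
}
NORMAL_DENSITIES = {
    "tumor": 300.0,  # PanCK/SOX10 also stains normal epithelium
    "helper_t": 50.0, "cytotoxic_t": 75.0,
    "treg": 10.0, "macrophage": 70.0, "other": 150.0,
}


def _uniform_disc(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_core(
    comp: CompositionParams,
    intensity: IntensityModel | None = None,
    attraction: AttractionParams | None = None,
    diameter_mm: float = 1.5,
    seed=None,
    sample_id: str = "S1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one TMA core; returns (cells, truth) data frames.

    ``cells`` follows the cell-table schema; ``truth`` carries the planted
    phenotype label and true marker-positivity vector per cell (columns
    ``true_<marker>``), suitable as a ground-truth sidecar.
    """
    if diameter_mm <= 0:
        raise ParameterError("diameter_mm must be > 0")
    rng = np.random.default_rng(seed)
    intensity = intensity or IntensityModel.default()
    attraction = attraction or AttractionParams()
    radius_um = diameter_mm * 1000.0 / 2.0
    area_mm2 = math.pi * (diameter_mm / 2.0) ** 2

    if (
        attraction.kappa > 0
        and comp.densities.get("cytotoxic_t", 0) > 0
        and comp.p_pd1_given_cd8 > 0
        and comp.densities.get("macrophage", 0) * comp.p_pdl1_given_cd68 == 0
    ):
        raise ParameterError(
            "attraction requested (kappa > 0) but the composition produces no "
            "PD-L1+CD68+ reference cells"
        )

    labels_list = []
    for ph in GENERATOR_PHENOTYPES:
        n_ph = rng.poisson(comp.densities.get(ph, 0.0) * area_mm2)
        labels_list.append(np.full(n_ph, ph))
    base = np.concatenate(labels_list) if labels_list else np.array([], dtype=object)
    n = len(base)

    xy = _uniform_disc(n, radius_um, rng)

    # true positivity matrix
    truth_pos = {m: np.zeros(n, dtype=bool) for m in MARKER_NAMES}
    truth_pos["dapi"][:] = True
    for ph, markers in _LINEAGE_MARKERS.items():
        mask = base == ph
        for m in markers:
            truth_pos[m][mask] = True
    cyto = base == "cytotoxic_t"
    mac = base == "macrophage"
    tum = base == "tumor"
    truth_pos["pd1"][cyto] = rng.uniform(size=int(cyto.sum())) < comp.p_pd1_given_cd8
    truth_pos["pdl1"][mac] = rng.uniform(size=int(mac.sum())) < comp.p_pdl1_given_cd68
    truth_pos["pdl1"][tum] = rng.uniform(size=int(tum.sum())) < comp.p_pdl1_given_tumor

    # attraction: move a kappa/(1+kappa) fraction of PD-1+CD8+ cells next to
    # randomly chosen PD-L1+CD68+ cells (Gaussian offsets, resampled into disc)
    if attraction.kappa > 0:
        queries = np.flatnonzero(cyto & truth_pos["pd1"])
        refs = np.flatnonzero(mac & truth_pos["pdl1"])
        if len(queries) and len(refs):
            move = queries[rng.uniform(size=len(queries)) < attraction.attracted_fraction]
            if len(move):
                parent = refs[rng.integers(len(refs), size=len(move))]
                pos = xy[parent] + rng.normal(0.0, attraction.sigma_um, size=(len(move), 2))
                for _ in range(200):
                    outside = np.einsum("ij,ij->i", pos, pos) > radius_um**2
                    if not outside.any():
                        break
                    k = int(outside.sum())
                    pos[outside] = xy[parent[outside]] + rng.normal(
                        0.0, attraction.sigma_um, size=(k, 2)
                    )
                else:  # pathological sigma; clamp the stragglers onto the rim
                    outside = np.einsum("ij,ij->i", pos, pos) > radius_um**2
                    norms = np.linalg.norm(pos[outside], axis=1)
                    pos[outside] *= (radius_um / norms)[:, None] * 0.999
                xy[move] = pos

    # intensities: log-normal from the positive component where truly positive
    intensities = {}
    for m in MARKER_NAMES:
        mix = intensity.mixtures[m]
        mu = np.where(truth_pos[m], mix.pos_log_mean, mix.neg_log_mean)
        sd = np.where(truth_pos[m], mix.pos_log_sd, mix.neg_log_sd)
        intensities[m] = np.exp(rng.normal(mu, sd))

    # final truth labels, matching the gating vocabulary
    label = np.full(n, "Other", dtype=object)
    label[base == "helper_t"] = "T_cell"
    label[base == "treg"] = "Treg"
    label[cyto] = np.where(truth_pos["pd1"][cyto], "Exhausted_cytotoxic_T", "Cytotoxic_T")
    label[mac] = np.where(truth_pos["pdl1"][mac], "PD-L1_Macrophage", "Macrophage")
    label[tum] = np.where(truth_pos["pdl1"][tum], "PD-L1_Tumor", "Tumor")

    cell_id = np.array([f"c{i:05d}" for i in range(n)])
    cells = pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": cell_id,
            "x_um": xy[:, 0] + radius_um,   # origin at bounding-box lower-left
            "y_um": xy[:, 1] + radius_um,
            **intensities,
        }
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": cell_id,
            "true_phenotype": label,
            **{f"true_{m}": truth_pos[m] for m in MARKER_NAMES},
        }
    )
    return cells, truth


def simulate_negative_control(
    intensity: IntensityModel | None = None,
    n_cells: int = 2000,
    seed=None,
    diameter_mm: float = 1.5,
    sample_id: str = "NEGCTRL",
) -> pd.DataFrame:
    """Negative-control core: every non-DAPI intensity from the negative model."""
    if n_cells <= 0:
        raise ParameterError("n_cells must be > 0")
    rng = np.random.default_rng(seed)
    intensity = intensity or IntensityModel.default()
    radius_um = diameter_mm * 1000.0 / 2.0
    xy = _uniform_disc(n_cells, radius_um, rng)
    cols = {}
    for m in MARKER_NAMES:
        mix = intensity.mixtures[m]
        if m == "dapi":
            cols[m] = np.exp(rng.normal(mix.pos_log_mean, mix.pos_log_sd, size=n_cells))
        else:
            cols[m] = np.exp(rng.normal(mix.neg_log_mean, mix.neg_log_sd, size=n_cells))
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": [f"c{i:05d}" for i in range(n_cells)],
            "x_um": xy[:, 0] + radius_um,
            "y_um": xy[:, 1] + radius_um,
            **cols,
        }
    )


# ---------------------------------------------------------------------------
# cohort level


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate a cohort (one tumor core per patient,
    optionally a paired adjacent-normal core, plus one negative-control slide).
    """

    n_patients: int = 84
    tumor_comp: CompositionParams = field(
        default_factory=lambda: CompositionParams(dict(TUMOR_DENSITIES))
    )
    normal_comp: CompositionParams | None = field(
        default_factory=lambda: CompositionParams(
            dict(NORMAL_DENSITIES),
            p_pd1_given_cd8=0.15, p_pdl1_given_cd68=0.15, p_pdl1_given_tumor=0.10,
        )
    )
    intensity: IntensityModel = field(default_factory=IntensityModel.default)
    attraction: AttractionParams = field(default_factory=lambda: AttractionParams(kappa=3.0))
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    #: cross-patient correlation of logit(p_pd1|cd8) and logit(p_pdl1|cd68)
    rho: float = 0.8
    pd1_logit_sd: float = 0.8
    pdl1_logit_sd: float = 0.8
    #: logit shift applied to both functional fractions in adjacent-normal cores
    normal_logit_offset: float = -1.2
    #: fraction of patients contributing a paired adjacent-normal core
    normal_fraction: float = 73.0 / 84.0
    n_control_cells: int = 2000
    core_diameter_mm: float = 1.5

    def __post_init__(self):
        if self.n_patients < 2:
            raise ParameterError("n_patients must be >= 2")
        if not -1.0 < self.rho < 1.0:
            raise ParameterError("rho must be in (-1, 1)")


def preset(name: str) -> CohortSpec:
    """Named cohort presets.

    ``pdac-like``: the default conditions (84 patients, 73 paired normals,
    correlated functional fractions, attraction kappa=3, proportion-dependent
    hazards).  ``null``: same geometry but no attraction, no covariate effect
    on survival, uncorrelated fractions.
    """
    if name == "pdac-like":
        return CohortSpec()
    if name == "null":
        return CohortSpec(
            attraction=AttractionParams(kappa=0.0),
            survival=SurvivalModel(coefficients={}, reference={}),
            rho=0.0,
        )
    raise ParameterError(f"unknown preset {name!r} (choose 'pdac-like' or 'null')")


@dataclass
class CohortData:
    """Simulated cohort: cell table, per-sample metadata, and ground truth."""

    cells: pd.DataFrame
    meta: pd.DataFrame
    cell_truth: pd.DataFrame
    patient_truth: pd.DataFrame

    def as_cell_table(self) -> CellTable:
        return CellTable(cells=self.cells, meta=self.meta).validate()


def simulate_survival_data(
    covariates: pd.DataFrame,
    model: SurvivalModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw (time, event) for each covariate row under the exponential PH model."""
    lp = model.linear_predictor(covariates)
    rate = model.baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if model.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / model.censoring_rate, size=len(covariates))
    else:
        t_cens = np.full(len(covariates), np.inf)
    t_cens = np.minimum(t_cens, model.max_followup)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    out = covariates.copy()
    out["survival_months"] = time
    out["event"] = event
    out["linear_predictor"] = lp
    return out


def simulate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> CohortData:
    """Simulate a full cohort under ``spec`` (default: the pdac-like preset)."""
    spec = spec or preset("pdac-like")
    ss = np.random.SeedSequence(seed)
    rng_patient, rng_surv, rng_ctrl, rng_cores = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    n = spec.n_patients

    # correlated per-patient functional fractions (logit scale)
    m1 = logit(spec.tumor_comp.p_pd1_given_cd8)
    m2 = logit(spec.tumor_comp.p_pdl1_given_cd68)
    cov = np.array(
        [
            [spec.pd1_logit_sd**2, spec.rho * spec.pd1_logit_sd * spec.pdl1_logit_sd],
            [spec.rho * spec.pd1_logit_sd * spec.pdl1_logit_sd, spec.pdl1_logit_sd**2],
        ]
    )
    logits = rng_patient.multivariate_normal([m1, m2], cov, size=n)
    p_pd1 = expit(logits[:, 0])
    p_pdl1 = expit(logits[:, 1])

    age = np.clip(rng_patient.normal(63.0, 9.0, size=n), 35.0, 88.0)
    sex_male = rng_patient.uniform(size=n) < 0.55
    stage = rng_patient.choice([1, 2, 3, 4], p=[0.15, 0.45, 0.25, 0.15], size=n)

    patient_ids = [f"P{i:03d}" for i in range(n)]
    covs = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "prop_pd1_cd8": p_pd1,
            "prop_pdl1_cd68": p_pdl1,
            "age": age,
            "sex_male": sex_male.astype(int),
            "stage": stage,
        }
    )
    patient_truth = simulate_survival_data(covs, spec.survival, rng_surv)

    n_normal = int(round(spec.normal_fraction * n)) if spec.normal_comp is not None else 0
    core_seeds = np.random.SeedSequence(
        entropy=rng_cores.integers(2**31)
    ).spawn(2 * n)

    cells_parts, meta_rows, truth_parts = [], [], []
    area = math.pi * (spec.core_diameter_mm / 2.0) ** 2
    for i, pid in enumerate(patient_ids):
        comp_t = replace(
            spec.tumor_comp,
            p_pd1_given_cd8=float(p_pd1[i]),
            p_pdl1_given_cd68=float(p_pdl1[i]),
        )
        sid = f"{pid}_T"
        cells, truth = simulate_core(
            comp_t, spec.intensity, spec.attraction,
            diameter_mm=spec.core_diameter_mm, seed=core_seeds[2 * i], sample_id=sid,
        )
        cells_parts.append(cells)
        truth_parts.append(truth)
        meta_rows.append(
            dict(sample_id=sid, patient_id=pid, tissue_class="tumor",
                 core_diameter_mm=spec.core_diameter_mm, tissue_area_mm2=area,
                 survival_months=patient_truth["survival_months"].iloc[i],
                 event=bool(patient_truth["event"].iloc[i]),
                 age=age[i], sex="M" if sex_male[i] else "F", stage=int(stage[i]))
        )
        if i < n_normal:
            comp_n = replace(
                spec.normal_comp,
                p_pd1_given_cd8=float(expit(logits[i, 0] + spec.normal_logit_offset)),
                p_pdl1_given_cd68=float(expit(logits[i, 1] + spec.normal_logit_offset)),
            )
            sid_n = f"{pid}_N"
            cells_n, truth_n = simulate_core(
                comp_n, spec.intensity, spec.attraction,
                diameter_mm=spec.core_diameter_mm, seed=core_seeds[2 * i + 1],
                sample_id=sid_n,
            )
            cells_parts.append(cells_n)
            truth_parts.append(truth_n)
            meta_rows.append(
                dict(sample_id=sid_n, patient_id=pid, tissue_class="adjacent_normal",
                     core_diameter_mm=spec.core_diameter_mm, tissue_area_mm2=area,
                     survival_months=patient_truth["survival_months"].iloc[i],
                     event=bool(patient_truth["event"].iloc[i]),
                     age=age[i], sex="M" if sex_male[i] else "F", stage=int(stage[i]))
            )

    if spec.n_control_cells > 0:
        ctrl = simulate_negative_control(
            spec.intensity, n_cells=spec.n_control_cells, seed=rng_ctrl,
            diameter_mm=spec.core_diameter_mm, sample_id="NEGCTRL",
        )
        cells_parts.append(ctrl)
        meta_rows.append(
            dict(sample_id="NEGCTRL", patient_id="", tissue_class="negative_control",
                 core_diameter_mm=spec.core_diameter_mm, tissue_area_mm2=area,
                 survival_months=np.nan, event=np.nan, age=np.nan, sex="", stage=np.nan)
        )

    cells = pd.concat(cells_parts, ignore_index=True)
    meta = pd.DataFrame(meta_rows)
    cell_truth = pd.concat(truth_parts, ignore_index=True)
    return CohortData(cells=cells, meta=meta, cell_truth=cell_truth,
                      patient_truth=patient_truth)
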
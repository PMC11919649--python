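"""Synthetic cohort generator: enrollment roster, tissue truths, lesion phantoms.

Emulates a breast-tumor study population: a collection roster with three
disjoint exclusion rules (small lesion, missing pathology, poor image
quality), a benign/malignant split with histology labels, immunohistochemical
(IHC) marker allocation for invasive breast cancer (IBC) cases matching fixed
marginal counts, per-lesion ground-truth tissue parameters drawn from
group-level truncated normals, and noisy 4D diffusion-weighted lesion
phantoms under an acquisition protocol.

Marginal label counts are matched exactly by deterministic allocation and
then shuffled by seed; the joint coupling between markers is random. Molecular
subtype labels are likewise allocated to fixed counts, and each record carries
a flag stating whether its subtype agrees with the rule implied by its
(ER, PR, HER-2) status:

    Luminal A     ER+ and/or PR+, HER-2-
    Luminal B     ER+ and/or PR+, HER-2+
    HER2over      ER- and PR-,    HER-2+
    TN            ER- and PR-,    HER-2-

The default composition's printed subtype counts are not jointly realizable
with its marker marginals (rule-derived Luminal B + HER2over counts would
need more HER-2+ cases than the HER-2 marginal allows), so full consistency
is impossible; :func:`check_subtype_feasibility` quantifies this.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fitting import fit_adc
from .protocol import adc_name
from .signal_model import (D_IN_DEFAULT, PARAM_BOUNDS, TissueParams,
                           TwoCompartmentModel)

__all__ = ["CohortSpec", "PatientRecord", "LesionPhantom",
           "generate_roster", "apply_exclusions", "draw_tissue_params",
           "generate_lesion_image", "cohort_table", "simulate_observer_pair",
           "subtype_from_markers", "check_subtype_feasibility"]

SUBTYPES = ("LuminalA", "LuminalB", "HER2over", "TN")


def subtype_from_markers(er: bool, pr: bool, her2: bool) -> str:
    """Molecular subtype implied by hormone-receptor and HER-2 status."""
    if er or pr:
        return "LuminalB" if her2 else "LuminalA"
    return "HER2over" if her2 else "TN"


@dataclass(frozen=True)
class CohortSpec:
    """Composition and distribution parameters of the synthetic cohort."""

    n_collected: int = 236
    exclusions: dict = field(default_factory=lambda: {
        "small_lesion": 10, "no_pathology": 5, "poor_quality": 8})
    n_benign: int = 83
    n_malignant: int = 130
    benign_histology: dict = field(default_factory=lambda: {
        "fibroadenoma": 47, "adenopathy": 15, "inflammatory_lesion": 6,
        "intraductal_papilloma": 5, "foliate_tumor": 10})
    malignant_histology: dict = field(default_factory=lambda: {
        "invasive_carcinoma": 113, "invasive_lobular_carcinoma": 4,
        "ductal_carcinoma_in_situ": 11, "lymphoma": 2})
    ibc_histologies: tuple = ("invasive_carcinoma", "invasive_lobular_carcinoma")
    er_pos: int = 87
    pr_pos: int = 73
    her2_pos: int = 46
    ki67_high: int = 104
    grades: dict = field(default_factory=lambda: {"I": 4, "II": 67, "III": 46})
    subtypes: dict = field(default_factory=lambda: {
        "LuminalA": 8, "LuminalB": 71, "HER2over": 26, "TN": 12})
    # group-level (mean, sd) of the tissue truth parameters
    param_distributions: dict = field(default_factory=lambda: {
        "benign": {"d_mean": (14.38, 4.645), "f_in": (0.279, 0.212),
                   "D_ex": (2.378, 0.332)},
        "malignant": {"d_mean": (15.74, 2.677), "f_in": (0.346, 0.125),
                      "D_ex": (2.119, 0.395)},
    })
    #: within-group correlation between d_mean and f_in draws (larger cells
    #: carry more intracellular volume); needed for the cellularity-index
    #: group contrast to point the right way under the printed marginals
    fd_correlation: float = 0.7
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path=None) -> "CohortSpec":
        """Load a spec from YAML (packaged default when ``path`` is None)."""
        import yaml
        from importlib import resources
        if path is None:
            text = resources.files("impulsed.data").joinpath(
                "cohort_default.yaml").read_text()
        else:
            from pathlib import Path
            text = Path(path).read_text()
        cfg = yaml.safe_load(text)
        if "param_distributions" in cfg:
            cfg["param_distributions"] = {
                g: {p: tuple(v) for p, v in dists.items()}
                for g, dists in cfg["param_distributions"].items()}
        if "ibc_histologies" in cfg:
            cfg["ibc_histologies"] = tuple(cfg["ibc_histologies"])
        return cls(**cfg)

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusions.values())

    @property
    def n_enrolled(self) -> int:
        return self.n_collected - self.n_excluded

    @property
    def n_ibc(self) -> int:
        return sum(self.malignant_histology.get(h, 0)
                   for h in self.ibc_histologies)

    def validate(self) -> None:
        if self.n_excluded > self.n_collected:
            raise ValueError("exclusion counts exceed the collection total")
        if self.n_benign + self.n_malignant != self.n_enrolled:
            raise ValueError("group sizes must sum to the enrolled count")
        if sum(self.benign_histology.values()) != self.n_benign:
            raise ValueError("benign histology counts do not sum to n_benign")
        if sum(self.malignant_histology.values()) != self.n_malignant:
            raise ValueError("malignant histology counts do not sum to n_malignant")
        n_ibc = self.n_ibc
        for name, k in [("er_pos", self.er_pos), ("pr_pos", self.pr_pos),
                        ("her2_pos", self.her2_pos), ("ki67_high", self.ki67_high)]:
            if not 0 <= k <= n_ibc:
                raise ValueError(f"{name}={k} outside [0, {n_ibc}]")
        if sum(self.grades.values()) != n_ibc:
            raise ValueError("grade counts do not sum to the IBC count")
        if sum(self.subtypes.values()) != n_ibc:
            raise ValueError("subtype counts do not sum to the IBC count")
        for group, dists in self.param_distributions.items():
            for pname, (mean, sd) in dists.items():
                lo, hi = PARAM_BOUNDS[pname]
                if not lo < mean < hi:
                    raise ValueError(f"{group}.{pname} mean {mean} outside bounds")


@dataclass
class PatientRecord:
    patient_id: str
    lesion_diameter_mm: float
    pathology_available: bool
    image_quality_ok: bool
    enrolled: bool
    exclusion_reason: str | None = None
    group: str | None = None  # benign | malignant
    histology: str | None = None
    is_ibc: bool = False
    er: str | None = None  # pos | neg
    pr: str | None = None
    her2: str | None = None
    ki67: str | None = None  # high | low
    grade: str | None = None
    subtype: str | None = None
    subtype_rule_consistent: bool | None = None
    truth: TissueParams | None = None


def check_subtype_feasibility(spec: CohortSpec) -> dict:
    """Compare printed subtype counts with what the marker marginals allow.

    Rule-derived HER-2+ subtypes (Luminal B + HER2over) can never exceed the
    HER-2+ marginal; returns the implied minimum number of rule-inconsistent
    records.
    """
    her2_pos_subtypes = spec.subtypes["LuminalB"] + spec.subtypes["HER2over"]
    deficit = max(0, her2_pos_subtypes - spec.her2_pos)
    return {"her2_pos_needed": her2_pos_subtypes, "her2_pos_available": spec.her2_pos,
            "min_inconsistent": deficit, "feasible": deficit == 0}


def _allocated_labels(rng: np.random.Generator, counts: dict) -> np.ndarray:
    """Exact-count label vector, shuffled."""
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(labels)
    return labels


def _allocated_flags(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def draw_tissue_params(spec: CohortSpec, group: str,
                       rng: np.random.Generator | int) -> TissueParams:
    """Normal draw of (d_mean, f_in, D_ex), clipped to the physical bounds.

    (d_mean, f_in) are drawn jointly with correlation ``spec.fd_correlation``;
    D_ex is independent. All draws are clipped to the open physiological box.
    """
    if group not in spec.param_distributions:
        raise ValueError(f"unknown stratum {group!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    dists = spec.param_distributions[group]
    eps = 1e-6
    mu_d, sd_d = dists["d_mean"]
    mu_f, sd_f = dists["f_in"]
    mu_x, sd_x = dists["D_ex"]
    rho = spec.fd_correlation
    z = rng.standard_normal(3)
    d = mu_d + sd_d * z[0]
    f = mu_f + sd_f * (rho * z[0] + np.sqrt(1.0 - rho * rho) * z[1])
    dex = mu_x + sd_x * z[2]
    lo_d, hi_d = PARAM_BOUNDS["d_mean"]
    lo_x, hi_x = PARAM_BOUNDS["D_ex"]
    return TissueParams(
        d_mean=float(np.clip(d, lo_d + eps, hi_d - eps)),
        f_in=float(np.clip(f, eps, 1.0 - eps)),
        D_ex=float(np.clip(dex, lo_x + eps, hi_x - eps)),
        D_in=D_IN_DEFAULT)


def generate_roster(spec: CohortSpec | None = None,
                    seed: int | None = None) -> list[PatientRecord]:
    """Full collection roster with exclusion flags, labels and tissue truths.

    Exclusion reasons are disjoint by construction (each excluded record fails
    exactly one rule). All label marginals are matched exactly by allocation;
    the coupling between markers is random under ``seed``.
    """
    spec = spec or CohortSpec()
    spec.validate()
    seed = spec.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = spec.n_collected

    status = _allocated_labels(rng, {**spec.exclusions,
                                     "enrolled": spec.n_enrolled})
    records: list[PatientRecord] = []
    for i, st in enumerate(status):
        small = st == "small_lesion"
        rec = PatientRecord(
            patient_id=f"P{i + 1:04d}",
            lesion_diameter_mm=float(rng.uniform(3.0, 7.9)) if small
            else float(rng.uniform(8.0, 45.0)),
            pathology_available=st != "no_pathology",
            image_quality_ok=st != "poor_quality",
            enrolled=st == "enrolled",
            exclusion_reason=None if st == "enrolled" else str(st),
        )
        records.append(rec)

    enrolled = [r for r in records if r.enrolled]
    groups = _allocated_labels(rng, {"benign": spec.n_benign,
                                     "malignant": spec.n_malignant})
    benign_hist = list(_allocated_labels(rng, spec.benign_histology))
    malignant_hist = list(_allocated_labels(rng, spec.malignant_histology))
    for rec, grp in zip(enrolled, groups):
        rec.group = str(grp)
        rec.histology = benign_hist.pop() if grp == "benign" else malignant_hist.pop()
        rec.is_ibc = rec.histology in spec.ibc_histologies
        rec.truth = draw_tissue_params(spec, rec.group, rng)

    ibc = [r for r in enrolled if r.is_ibc]
    n_ibc = len(ibc)
    er = _allocated_flags(rng, n_ibc, spec.er_pos)
    pr = _allocated_flags(rng, n_ibc, spec.pr_pos)
    her2 = _allocated_flags(rng, n_ibc, spec.her2_pos)
    ki67 = _allocated_flags(rng, n_ibc, spec.ki67_high)
    grade = _allocated_labels(rng, spec.grades)
    subtype = _allocated_labels(rng, spec.subtypes)
    for i, rec in enumerate(ibc):
        rec.er = "pos" if er[i] else "neg"
        rec.pr = "pos" if pr[i] else "neg"
        rec.her2 = "pos" if her2[i] else "neg"
        rec.ki67 = "high" if ki67[i] else "low"
        rec.grade = str(grade[i])
        rec.subtype = str(subtype[i])
        rec.subtype_rule_consistent = (
            rec.subtype == subtype_from_markers(er[i], pr[i], her2[i]))
    return records


def apply_exclusions(roster: list[PatientRecord]) -> tuple[list[PatientRecord], dict]:
    """Filter the roster by the three exclusion rules, in their stated order.

    Returns the enrolled cohort and a per-rule exclusion count report; a
    record failing several rules is counted once, under the first rule.
    """
    report = {"small_lesion": 0, "no_pathology": 0, "poor_quality": 0}
    cohort = []
    for rec in roster:
        if rec.lesion_diameter_mm < 8.0:
            report["small_lesion"] += 1
        elif not rec.pathology_available:
            report["no_pathology"] += 1
        elif not rec.image_quality_ok:
            report["poor_quality"] += 1
        else:
            cohort.append(rec)
    return cohort, report


@dataclass
class LesionPhantom:
    """4D synthetic signal volume with its mask and ground-truth maps."""

    volume4d: np.ndarray
    mask: np.ndarray
    truth_maps: dict
    shells: list


def generate_lesion_image(truth: TissueParams, model: TwoCompartmentModel,
                          shape: tuple[int, int, int] = (12, 12, 3),
                          snr: float = 50.0, seed: int = 0,
                          jitter_cv: float = 0.05,
                          mask: np.ndarray | None = None) -> LesionPhantom:
    """Noisy 4D lesion phantom under the model's protocol.

    Voxels inside the mask get forward signals from ``truth`` with per-voxel
    lognormal parameter jitter of coefficient of variation ``jitter_cv``
    (clipped to the physical bounds); Rician noise of scale S0/snr is applied
    as the magnitude of a complex Gaussian perturbation (``snr=np.inf``
    disables it). Background voxels are noise-only.
    """
    if not snr > 0:
        raise ValueError("snr must be positive (np.inf for noiseless)")
    rng = np.random.default_rng(seed)
    shells = model.protocol.shells()
    if mask is None:
        mask = np.zeros(shape, dtype=bool)
        cx, cy = shape[0] // 2, shape[1] // 2
        r = max(2, min(shape[0], shape[1]) // 3)
        xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        mask[:, :, shape[2] // 2] = disk
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != shape:
            raise ValueError("mask shape must match the phantom shape")

    eps = 1e-6
    truth_maps = {k: np.full(shape, np.nan)
                  for k in ("d_mean", "f_in", "D_ex", "cellularity")}
    vol = np.zeros(shape + (len(shells),))
    for ijk in np.argwhere(mask):
        jit = rng.lognormal(mean=0.0, sigma=jitter_cv, size=3) if jitter_cv > 0 \
            else np.ones(3)
        d = float(np.clip(truth.d_mean * jit[0],
                          PARAM_BOUNDS["d_mean"][0] + eps,
                          PARAM_BOUNDS["d_mean"][1] - eps))
        f = float(np.clip(truth.f_in * jit[1], eps, 1 - eps))
        dex = float(np.clip(truth.D_ex * jit[2],
                            PARAM_BOUNDS["D_ex"][0] + eps,
                            PARAM_BOUNDS["D_ex"][1] - eps))
        vol[tuple(ijk)] = model.predict(d, f, dex, shells)
        truth_maps["d_mean"][tuple(ijk)] = d
        truth_maps["f_in"][tuple(ijk)] = f
        truth_maps["D_ex"][tuple(ijk)] = dex
        truth_maps["cellularity"][tuple(ijk)] = f / d

    if np.isfinite(snr):
        sigma = 1.0 / snr  # S0 is 1 by construction
        re = vol + rng.normal(0.0, sigma, vol.shape)
        im = rng.normal(0.0, sigma, vol.shape)
        vol = np.sqrt(re * re + im * im)
    return LesionPhantom(volume4d=vol, mask=mask, truth_maps=truth_maps,
                         shells=shells)


def _adc_truths(truth: TissueParams, model: TwoCompartmentModel) -> dict:
    """Per-sequence mono-exponential ADC implied by the forward model."""
    out = {}
    for seq in model.protocol.sequences:
        shells = [(seq.label, b) for b in seq.b_values]
        sig = model.predict(truth.d_mean, truth.f_in, truth.D_ex, shells)
        out[adc_name(seq.label)] = fit_adc([b for _, b in shells], sig,
                                           seq.label).adc
    return out


def cohort_table(records: list[PatientRecord],
                 model: TwoCompartmentModel | None = None) -> pd.DataFrame:
    """One row per enrolled lesion: labels, truths and model-implied ADCs."""
    rows = []
    for rec in records:
        if not rec.enrolled:
            continue
        row = {
            "patient_id": rec.patient_id,
            "group": rec.group,
            "histology": rec.histology,
            "is_ibc": rec.is_ibc,
            "er": rec.er, "pr": rec.pr, "her2": rec.her2, "ki67": rec.ki67,
            "grade": rec.grade, "subtype": rec.subtype,
            "subtype_rule_consistent": rec.subtype_rule_consistent,
            "d_mean": rec.truth.d_mean,
            "f_in": rec.truth.f_in,
            "D_ex": rec.truth.D_ex,
            "cellularity": rec.truth.cellularity,
        }
        if model is not None:
            row.update(_adc_truths(rec.truth, model))
        rows.append(row)
    return pd.DataFrame(rows)


def roster_table(records: list[PatientRecord]) -> pd.DataFrame:
    """Flat roster table (one row per collected patient)."""
    rows = []
    for rec in records:
        d = asdict(rec)
        truth = d.pop("truth")
        if truth is not None:
            d.update({k: truth[k] for k in ("d_mean", "f_in", "D_ex")})
        rows.append(d)
    return pd.DataFrame(rows)


def simulate_observer_pair(values, seed: int = 0,
                           noise_var_ratio: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Two simulated observers' measurements of the same quantities.

    Each observer adds independent zero-mean Gaussian noise with variance
    ``noise_var_ratio`` times the between-lesion variance; the default ratio
    0.2 targets an intraclass correlation near 1/1.2 ~ 0.83.
    """
    rng = np.random.default_rng(seed)
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1)) * np.sqrt(noise_var_ratio)
    return (v + rng.normal(0, sd, v.size), v + rng.normal(0, sd, v.size))
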
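"""Synthetic multiplex-plate datasets with known ground truth.

The generator emulates the structure of a three-plate cytokine inflammation
panel study: 169 patients contributing 191 samples over four tissue types
(plasma, saliva, serum, urine) and eight conditions (Normal plus seven
diseases), 37 analytes per well, duplicate sample wells, an 8-point
standard dilution series plus blank per analyte and plate, and half-unit
quantization of the reported median fluorescence.

The latent model mirrors the mixed model the analyses assume: the log2
concentration of sample i, analyte a is

    baseline_a + tissue_effect(a, t) + condition_effect(a, c)
    + patient_effect + plate_group_effect + residual

with the two random effects crossed.  Fluorescence is the analyte's 5PL
curve evaluated at the latent concentration times multiplicative lognormal
noise (constant-CV, the error model behind %CV reporting), then quantized.
Analyte baselines are spread so a low-abundance subset (~9 of 37) sits
below its lowest standard, which is what makes concentration censoring
bite while fluorescence analysis proceeds untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_data import COLUMNS, PlateDataset, ConfigurationError
from .standard_curve import FivePLFit, _fivepl_raw

TISSUES = ("plasma", "saliva", "serum", "urine")
CONDITIONS = ("Normal", "COPD", "Mono", "Myeloma", "Psoriasis", "RA",
              "Sepsis", "T2D")

#: Default sample allocation: (condition, tissue, plate, n_samples, paired_set)
#: Paired sets re-use the same patients across their two tissues.
#: 14 nonempty plate:condition:tissue groups; 191 samples from 169 patients
#: (16 mononucleosis + 6 myeloma patients each give plasma and serum).
DEFAULT_ALLOCATION = (
    ("Normal", "plasma", "plate1", 25, None),
    ("Normal", "saliva", "plate1", 15, None),
    ("Normal", "serum", "plate2", 20, None),
    ("Normal", "urine", "plate2", 15, None),
    ("Mono", "plasma", "plate1", 16, "mononucleosis"),
    ("Mono", "serum", "plate1", 16, "mononucleosis"),
    ("Myeloma", "plasma", "plate2", 6, "myeloma"),
    ("Myeloma", "serum", "plate2", 6, "myeloma"),
    ("COPD", "plasma", "plate3", 14, None),
    ("Psoriasis", "plasma", "plate3", 14, None),
    ("RA", "serum", "plate3", 15, None),
    ("Sepsis", "plasma", "plate3", 14, None),
    ("T2D", "plasma", "plate3", 8, None),
    ("T2D", "serum", "plate3", 7, None),
)

_ANALYTE_NAMES = (
    "April (42)", "Baff (37)", "CD163 (46)", "CD30 (53)", "Chitinase (72)",
    "gp130 (14)", "IFN-a2 (20)", "IFN-b (44)", "IFN-g (21)", "IL-10 (56)",
    "IL-11 (39)", "IL-12p40 (28)", "IL-12p70 (75)", "IL-19 (29)", "IL-2 (38)",
    "IL-20 (30)", "IL-22 (18)", "IL-26 (22)", "IL-27 (13)", "IL-28 (66)",
    "IL-29 (33)", "IL-32 (35)", "IL-34 (15)", "IL-35 (34)", "IL-6RA (19)",
    "IL-8 (54)", "Light (51)", "MMP-1 (43)", "MMP-2 (26)", "MMP-3 (45)",
    "OCN (65)", "OPN (77)", "Pentraxin (48)", "TNFR1 (73)", "TNFR2 (67)",
    "TSLP (52)", "Tweak (62)",
)


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the generator.

    Defaults reproduce the reference study conditions; ``small`` builds a
    reduced balanced design for fast simulation studies.
    """

    n_analytes: int = 37
    allocation: tuple = DEFAULT_ALLOCATION
    var_patient: float = 0.25       # log2^2 units
    var_plategroup: float = 0.09
    var_resid: float = 0.04
    effect_sd_tissue: float = 0.5   # sd of per-analyte tissue shifts, log2
    effect_sd_condition: float = 0.5
    baseline_low: float = -5.0      # per-analyte latent log2 conc means are
    baseline_high: float = 11.0     # spread over [low, high]; with 4-fold
                                    # standards from 10000 pg/ml this puts
                                    # ~9 of 37 analytes below the lowest standard
    fl_noise_sd_log2: float = 0.1   # multiplicative measurement noise (~7% CV)
    n_standards: int = 8
    standard_top_conc: float = 10000.0
    standard_dilution_factor: float = 4.0
    replicates: int = 2
    blank_mean_low_log2: float = 3.0   # analyte blank means drawn in
    blank_mean_high_log2: float = 7.0  # 2^[low, high] fluorescence units
    blank_cv: float = 0.1
    quantization_step: float = 0.5
    readout: str = "fivepl"         # "fivepl" | "linear" (fl = 2^latent;
                                    # the identity-curve limit, used to
                                    # isolate the mixed-model machinery)
    seed: int = 0
    analyte_baselines: np.ndarray | None = None
    tissue_effects: np.ndarray | None = None      # (n_analytes, n_tissues)
    condition_effects: np.ndarray | None = None   # (n_analytes, n_conditions)
    curve_params: list | None = None

    @classmethod
    def small(cls, n_analytes: int = 10, n_tissues: int = 4,
              n_conditions: int = 4, n_per_cell: int = 6, n_plates: int = 2,
              seed: int = 0, **kw) -> "GeneratorConfig":
        """Reduced balanced design: every condition x tissue populated,
        alternating plates, independent patients."""
        tissues = TISSUES[:n_tissues]
        conditions = CONDITIONS[:n_conditions]
        alloc = []
        for c in conditions:
            for t in tissues:
                # spread every cell over all plates so plate-group deviations
                # are observable within cells (the full design achieves this
                # through shared conditions across plates)
                for k in range(n_plates):
                    alloc.append((c, t, f"plate{k + 1}", n_per_cell, None))
        return cls(n_analytes=n_analytes, allocation=tuple(alloc), seed=seed,
                   **kw)


@dataclass
class GroundTruth:
    """Everything the generator drew, for recovery experiments."""

    latents: pd.DataFrame            # sample_id x analyte latent log2 conc
    sample_design: pd.DataFrame      # sample_id, patient, tissue, condition, plate
    patient_effects: dict
    plategroup_effects: dict
    analyte_baselines: np.ndarray
    tissue_effects: np.ndarray
    condition_effects: np.ndarray
    curve_params: list
    blank_means: np.ndarray
    config: GeneratorConfig = field(repr=False, default=None)


def quantize_fluorescence(values, step: float = 0.5):
    """Round fluorescence to the instrument's reporting resolution."""
    if step <= 0:
        raise ValueError("step must be positive")
    v = np.asarray(values, dtype=float)
    out = np.round(v / step) * step
    return float(out) if out.ndim == 0 else out


def _default_curves(rng, n_analytes):
    curves = []
    for _ in range(n_analytes):
        bottom = rng.uniform(20.0, 60.0)
        top = rng.uniform(15000.0, 25000.0)
        ec50 = float(np.exp2(rng.uniform(4.0, 8.0)))   # 16 .. 256 pg/ml
        hill = rng.uniform(0.8, 1.3)
        asym = rng.uniform(0.7, 1.4)
        curves.append(FivePLFit(bottom=bottom, top=top, ec50=ec50,
                                hill=hill, asym=asym, weight_mode="none"))
    return curves


def _allocate_samples(config, rng):
    """Expand the allocation table into per-sample design rows."""
    paired_patients = {}
    rows = []
    counter = 0
    for cond, tissue, plate, n, paired in config.allocation:
        if paired is not None:
            ids = paired_patients.get(paired)
            if ids is None:
                ids = [f"P{counter + i:03d}" for i in range(n)]
                counter += n
                paired_patients[paired] = ids
            elif len(ids) != n:
                raise ConfigurationError(
                    f"paired set {paired!r} has inconsistent sizes")
        else:
            ids = [f"P{counter + i:03d}" for i in range(n)]
            counter += n
        for pid in ids:
            rows.append({"sample_id": f"{pid}:{tissue}", "patient_id": pid,
                         "tissue": tissue, "condition": cond, "plate": plate})
    design = pd.DataFrame(rows)
    if design["sample_id"].duplicated().any():
        raise ConfigurationError("allocation assigns a patient the same "
                                 "tissue twice")
    return design


def generate_dataset(config: GeneratorConfig) -> tuple[PlateDataset, GroundTruth]:
    """Draw a full plate dataset plus its ground truth.

    Identical configs (including seed) reproduce the dataset bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    n_a = config.n_analytes
    analytes = list(_ANALYTE_NAMES[:n_a])
    if n_a > len(_ANALYTE_NAMES):
        analytes += [f"Analyte-{i}" for i in range(len(_ANALYTE_NAMES), n_a)]

    tissues = sorted({a[1] for a in config.allocation})
    conditions = sorted({a[0] for a in config.allocation})

    baselines = (np.asarray(config.analyte_baselines, dtype=float)
                 if config.analyte_baselines is not None
                 else np.linspace(config.baseline_low, config.baseline_high, n_a))
    t_eff = (np.asarray(config.tissue_effects, dtype=float)
             if config.tissue_effects is not None
             else rng.normal(0.0, config.effect_sd_tissue, (n_a, len(tissues))))
    c_eff = (np.asarray(config.condition_effects, dtype=float)
             if config.condition_effects is not None
             else rng.normal(0.0, config.effect_sd_condition,
                             (n_a, len(conditions))))
    curves = (config.curve_params if config.curve_params is not None
              else _default_curves(rng, n_a))
    blank_means = np.exp2(rng.uniform(config.blank_mean_low_log2,
                                      config.blank_mean_high_log2, n_a))

    design = _allocate_samples(config, rng)
    design["plate_group"] = (design["plate"] + ":" + design["condition"]
                             + ":" + design["tissue"])

    patients = sorted(design["patient_id"].unique())
    pgroups = sorted(design["plate_group"].unique())
    p_eff = dict(zip(patients,
                     rng.normal(0.0, np.sqrt(config.var_patient), len(patients))))
    g_eff = dict(zip(pgroups,
                     rng.normal(0.0, np.sqrt(config.var_plategroup), len(pgroups))))

    t_idx = {t: i for i, t in enumerate(tissues)}
    c_idx = {c: i for i, c in enumerate(conditions)}
    n_s = len(design)
    # latent log2 concentration per sample x analyte
    latent = (
        baselines[None, :]
        + t_eff[:, [t_idx[t] for t in design["tissue"]]].T
        + c_eff[:, [c_idx[c] for c in design["condition"]]].T
        + np.array([p_eff[p] for p in design["patient_id"]])[:, None]
        + np.array([g_eff[g] for g in design["plate_group"]])[:, None]
        + rng.normal(0.0, np.sqrt(config.var_resid), (n_s, n_a))
    )

    records = []
    step = config.quantization_step
    for j, analyte in enumerate(analytes):
        curve = curves[j]
        if config.readout == "linear":
            true_fl = np.exp2(latent[:, j])
        else:
            true_fl = _fivepl_raw(np.exp2(latent[:, j]), curve.bottom,
                                  curve.top, curve.ec50, curve.hill,
                                  curve.asym)
        for _ in range(config.replicates):
            noise = np.exp2(rng.normal(0.0, config.fl_noise_sd_log2, n_s))
            fl = quantize_fluorescence(np.maximum(true_fl * noise, step), step)
            rec = pd.DataFrame({
                "patient_id": design["patient_id"],
                "tissue": design["tissue"],
                "condition": design["condition"],
                "plate": design["plate"],
                "analyte": analyte,
                "well_role": "sample",
                "standard_level": np.nan,
                "fluorescence": fl,
                "concentration": np.nan,
                "censor_status": "unset",
            })
            records.append(rec)

    # standards: n_standards-point dilution series, in replicate wells
    plates = sorted(design["plate"].unique())
    std_concs = config.standard_top_conc / (
        config.standard_dilution_factor ** np.arange(config.n_standards))
    n_std_wells = len(plates) * config.n_standards * config.replicates
    n_blank_wells = len(plates) * config.replicates
    for j, analyte in enumerate(analytes):
        curve = curves[j]
        true_fl = _fivepl_raw(std_concs, curve.bottom, curve.top, curve.ec50,
                              curve.hill, curve.asym)
        true_fl = np.tile(np.repeat(true_fl, config.replicates), len(plates))
        noise = np.exp2(rng.normal(0.0, config.fl_noise_sd_log2, n_std_wells))
        fl = quantize_fluorescence(np.maximum(true_fl * noise, step), step)
        records.append(pd.DataFrame({
            "patient_id": "standard", "tissue": "", "condition": "",
            "plate": np.repeat(plates, config.n_standards * config.replicates),
            "analyte": analyte, "well_role": "standard",
            "standard_level": np.tile(
                np.repeat(np.arange(1, config.n_standards + 1),
                          config.replicates), len(plates)),
            "fluorescence": fl,
            "concentration": np.tile(np.repeat(std_concs, config.replicates),
                                     len(plates)),
            "censor_status": "unset",
        }))
        bl = rng.normal(blank_means[j], config.blank_cv * blank_means[j],
                        n_blank_wells)
        records.append(pd.DataFrame({
            "patient_id": "blank", "tissue": "", "condition": "",
            "plate": np.repeat(plates, config.replicates),
            "analyte": analyte, "well_role": "blank",
            "standard_level": np.nan,
            "fluorescence": quantize_fluorescence(np.maximum(bl, step), step),
            "concentration": np.nan,
            "censor_status": "unset",
        }))

    df = pd.concat(records, ignore_index=True)[COLUMNS]
    ds = PlateDataset(df)
    truth = GroundTruth(
        latents=pd.DataFrame(latent, index=design["sample_id"],
                             columns=analytes),
        sample_design=design,
        patient_effects=p_eff,
        plategroup_effects=g_eff,
        analyte_baselines=baselines,
        tissue_effects=t_eff,
        condition_effects=c_eff,
        curve_params=curves,
        blank_means=blank_means,
        config=config,
    )
    return ds, truth


def inject_low_abundance(ds: PlateDataset, analytes, depth: float = 1.0,
                         step: float | None = None) -> PlateDataset:
    """Shift analytes so their median response sits below the blank mean.

    ``depth`` is in log2 units: after the shift the analyte's median sample
    fluorescence equals ``blank_mean * 2**(-depth)``.  Used to exercise the
    oor_low censoring path (concentration cells empty, fluorescence intact).
    """
    out = ds.df.copy()
    step = step if step is not None else 0.5
    for analyte in analytes:
        m_sample = (out["well_role"] == "sample") & (out["analyte"] == analyte)
        m_blank = (out["well_role"] == "blank") & (out["analyte"] == analyte)
        if not m_sample.any() or not m_blank.any():
            continue
        blank_mean = out.loc[m_blank, "fluorescence"].mean()
        target = blank_mean * 2.0 ** (-depth)
        shift = out.loc[m_sample, "fluorescence"].median() - target
        shifted = np.maximum(out.loc[m_sample, "fluorescence"] - shift, step)
        out.loc[m_sample, "fluorescence"] = quantize_fluorescence(shifted, step)
    return PlateDataset(out, ds.log_base)
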
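"""Synthetic cohorts with known ground truth.

Generates everything the downstream stages consume, with the statistical
structure the analyses assume planted and recoverable:

* a clinical table (persons with amblyopia, PWA, and normally sighted
  persons, NSP) whose interocular acuity difference ("depth of amblyopia",
  D = logMAR NDE - logMAR DE) is rank-correlated with true visual-cortical
  GABA:Cr through a Gaussian copula,
* MEGA-PRESS scan bundles (16 On + 16 Off block spectra of 1,024 complex
  points) whose noiseless GABA:Cr integration ratio equals the planted value,
* per-condition 4AFC staircase trial logs from Weibull observers whose
  thresholds are elevated by eye-, configuration- and orientation-specific
  surround weights.

The packaged clinical fixture ``table1_pwa.csv`` holds the 16 PWA records
(ages, acuities, amblyopia types) used by the desk-scale checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import mrs
from .staircase import (StaircaseConfig, WeibullObserver, run_staircase,
                        TRIAL_COLUMNS)

EYES = ("DE", "NDE")
CONFIGS = ("monocular", "dichoptic")
ORIENTATIONS = ("iso", "cross")

#: Relative (multiples of the DE baseline threshold) surround-contrast set
#: tested for every condition of a subject; 3-5 values per subject in the
#: emulated design, individually scaled so thresholds are measurable.
DEFAULT_RELATIVE_SURROUNDS = (2.0, 4.0, 6.0, 10.0)


def default_suppression_weights() -> dict:
    """Surround weights w in multiplier = 1 + w * C-hat, keyed by
    (group, annulus eye, ocular configuration, orientation).

    Iso-oriented surrounds suppress more than cross-oriented ones; in PWA the
    dominant eye suppresses the amblyopic eye (dichoptic, NDE annulus) far
    more than the reverse, and monocular suppression is stronger in the NDE.
    NSP weights are eye-symmetric.
    """
    w = {}
    for eye in EYES:
        w[("NSP", eye, "dichoptic", "iso")] = 0.35
        w[("NSP", eye, "dichoptic", "cross")] = 0.15
        w[("NSP", eye, "monocular", "iso")] = 0.50
        w[("NSP", eye, "monocular", "cross")] = 0.22
    w[("PWA", "NDE", "dichoptic", "iso")] = 0.90
    w[("PWA", "NDE", "dichoptic", "cross")] = 0.50
    w[("PWA", "DE", "dichoptic", "iso")] = 0.15
    w[("PWA", "DE", "dichoptic", "cross")] = 0.06
    w[("PWA", "NDE", "monocular", "iso")] = 0.60
    w[("PWA", "NDE", "monocular", "cross")] = 0.28
    w[("PWA", "DE", "monocular", "iso")] = 0.45
    w[("PWA", "DE", "monocular", "cross")] = 0.20
    return w


def null_suppression_weights(w: float = 0.3) -> dict:
    """Eye- and orientation-symmetric weights (no planted asymmetry)."""
    return {(g, e, c, o): w for g in ("PWA", "NSP") for e in EYES
            for c in CONFIGS for o in ORIENTATIONS}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate the reported sample: 16 PWA and 15 NSP, GABA:Cr about
    0.09, and a planted rank correlation of -0.61 between visual-cortical
    GABA:Cr and depth of amblyopia among PWA.
    """

    n_pwa: int = 16
    n_nsp: int = 15
    rho_gaba_depth: float = -0.61
    gaba_mean: float = 0.09
    gaba_sd: float = 0.004
    acuity_de_range: tuple = (-0.20, 0.08)       # logMAR, PWA fellow eye
    acuity_nde_range: tuple = (0.12, 1.26)       # logMAR, PWA amblyopic eye
    suppression_weights: dict = field(default_factory=default_suppression_weights)
    observer_slope: float = 3.0                  # Weibull beta
    observer_lapse: float = 0.02
    snr_spectra: float = 120.0                   # block-spectrum Cr amplitude SNR
    relative_surrounds: tuple = DEFAULT_RELATIVE_SURROUNDS
    baseline_de_median: float = 0.03             # Michelson increment threshold
    seed: int = 0

    def validate(self) -> None:
        if self.n_pwa < 3:
            raise ValueError("n_pwa must be at least 3")
        if self.n_nsp < 3:
            raise ValueError("n_nsp must be at least 3")
        if abs(self.rho_gaba_depth) > 1:
            raise ValueError("rho_gaba_depth must lie in [-1, 1]")
        if self.gaba_sd <= 0:
            raise ValueError("gaba_sd must be positive")
        if self.snr_spectra <= 0:
            raise ValueError("snr_spectra must be positive")
        if any(w < 0 for w in self.suppression_weights.values()):
            raise ValueError("suppression_weights must be non-negative")
        if not 0 < self.baseline_de_median < 1:
            raise ValueError("baseline_de_median must lie in (0, 1)")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                      # "PWA" | "NSP"
    age: float
    sex: str                        # "F" | "M"
    amb_type: str                   # "Aniso" | "Mixed" | "none"
    amb_eye: str                    # "OS" | "OD" | "none"
    acuity_de: float                # logMAR
    acuity_nde: float               # logMAR
    stereo_arcsec: float = float("nan")
    mrs_quality_flag: bool = False  # True = discard MRS data

    def __post_init__(self):
        if self.group == "PWA" and not self.acuity_nde > self.acuity_de:
            raise ValueError(
                f"{self.subject_id}: PWA amblyopic-eye acuity must be worse "
                f"(NDE {self.acuity_nde} <= DE {self.acuity_de})")

    @property
    def depth(self) -> float:
        """Depth of amblyopia: interocular logMAR acuity difference."""
        return self.acuity_nde - self.acuity_de


@dataclass
class GroundTruth:
    """Planted values used as the recovery oracle for all downstream stages."""

    gaba_visual: dict               # subject_id -> true GABA:Cr, visual voxel
    gaba_motor: dict                # subject_id -> true GABA:Cr, control voxel
    baseline: dict                  # (subject_id, eye) -> Michelson threshold
    surround_contrasts: dict        # subject_id -> list of absolute Michelson
    multiplier: dict                # (sid, eye, config, orientation, C) -> m >= 1

    def cell_threshold(self, sid, eye, config, orientation, c) -> float:
        return self.baseline[(sid, eye)] * self.multiplier[(sid, eye, config, orientation, c)]

    def to_json(self, path: str) -> None:
        def enc(d):
            return {"|".join(map(str, k)) if isinstance(k, tuple) else k: v
                    for k, v in d.items()}
        with open(path, "w") as fh:
            json.dump({name: enc(getattr(self, name)) for name in
                       ("gaba_visual", "gaba_motor", "baseline",
                        "surround_contrasts", "multiplier")}, fh, indent=1)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _copula_pearson(rho_spearman: float) -> float:
    """Gaussian-copula Pearson correlation giving a target Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


def generate_cohort(spec: CohortSpec) -> tuple[list, GroundTruth]:
    """Draw a cohort: clinical records plus the full ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = []
    gaba_visual, gaba_motor = {}, {}
    baseline, surrounds, multiplier = {}, {}, {}

    r = _copula_pearson(spec.rho_gaba_depth)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=spec.n_pwa,
                                method="cholesky")
    de_lo, de_hi = spec.acuity_de_range
    nde_lo, nde_hi = spec.acuity_nde_range
    for i in range(spec.n_pwa):
        sid = f"P{i + 1:02d}"
        gaba = max(spec.gaba_mean + spec.gaba_sd * z[i, 0], 1e-3)
        u = norm.cdf(z[i, 1])
        acuity_de = rng.uniform(de_lo, de_hi)
        acuity_nde = nde_lo + u * (nde_hi - nde_lo)
        records.append(SubjectRecord(
            subject_id=sid, group="PWA",
            age=float(rng.integers(18, 63)),
            sex="F" if rng.random() < 10 / 16 else "M",
            amb_type="Aniso" if rng.random() < 12 / 16 else "Mixed",
            amb_eye="OS" if rng.random() < 0.7 else "OD",
            acuity_de=float(acuity_de), acuity_nde=float(acuity_nde)))
        gaba_visual[sid] = float(gaba)
        gaba_motor[sid] = float(max(spec.gaba_mean + spec.gaba_sd * rng.standard_normal(), 1e-3))

    for i in range(spec.n_nsp):
        sid = f"N{i + 1:02d}"
        acuity_de = float(rng.normal(0.0, 0.06))
        acuity_nde = float(acuity_de + rng.normal(0.0, 0.02))
        records.append(SubjectRecord(
            subject_id=sid, group="NSP",
            age=float(rng.integers(18, 63)),
            sex="F" if rng.random() < 0.5 else "M",
            amb_type="none", amb_eye="none",
            acuity_de=acuity_de, acuity_nde=acuity_nde))
        gaba_visual[sid] = float(max(spec.gaba_mean + spec.gaba_sd * rng.standard_normal(), 1e-3))
        gaba_motor[sid] = float(max(spec.gaba_mean + spec.gaba_sd * rng.standard_normal(), 1e-3))

    for rec in records:
        sid = rec.subject_id
        t_de = spec.baseline_de_median * 10.0 ** rng.normal(0.0, 0.08)
        if rec.group == "PWA":
            t_nde = t_de * (1.0 + 1.5 * rec.depth) * 10.0 ** rng.normal(0.0, 0.05)
        else:
            t_nde = t_de * 10.0 ** abs(rng.normal(0.0, 0.05))
        baseline[(sid, "DE")] = float(t_de)
        baseline[(sid, "NDE")] = float(t_nde)
        cs = [float(min(t_de * rel, 0.95)) for rel in spec.relative_surrounds]
        surrounds[sid] = cs
        for eye in EYES:
            for cfg in CONFIGS:
                for ori in ORIENTATIONS:
                    w = spec.suppression_weights[(rec.group, eye, cfg, ori)]
                    for c in cs:
                        c_hat = c / baseline[(sid, eye)]
                        m = 1.0 + w * c_hat
                        # keep generating thresholds measurably below the
                        # response ceiling (increment <= 1 - pedestal)
                        m = min(m, 0.60 / baseline[(sid, eye)])
                        multiplier[(sid, eye, cfg, ori, c)] = float(m)

    truth = GroundTruth(gaba_visual=gaba_visual, gaba_motor=gaba_motor,
                        baseline=baseline, surround_contrasts=surrounds,
                        multiplier=multiplier)
    return records, truth


# ---------------------------------------------------------------------------
# Clinical-table IO and the packaged fixture
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ["subject_id", "group", "age", "sex", "amb_type", "amb_eye",
                    "acuity_de_logmar", "acuity_nde_logmar", "stereo_arcsec",
                    "mrs_quality_flag"]


def records_to_frame(records) -> pd.DataFrame:
    rows = [{"subject_id": r.subject_id, "group": r.group, "age": r.age,
             "sex": r.sex, "amb_type": r.amb_type, "amb_eye": r.amb_eye,
             "acuity_de_logmar": r.acuity_de, "acuity_nde_logmar": r.acuity_nde,
             "stereo_arcsec": r.stereo_arcsec,
             "mrs_quality_flag": r.mrs_quality_flag} for r in records]
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list:
    records = []
    for _, row in frame.iterrows():
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            age=float(row["age"]), sex=str(row["sex"]),
            amb_type=str(row["amb_type"]), amb_eye=str(row["amb_eye"]),
            acuity_de=float(row["acuity_de_logmar"]),
            acuity_nde=float(row["acuity_nde_logmar"]),
            stereo_arcsec=(float(row["stereo_arcsec"])
                           if pd.notna(row["stereo_arcsec"]) else float("nan")),
            mrs_quality_flag=_parse_bool(row["mrs_quality_flag"])))
    return records


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1", "yes")


def load_table1_fixture() -> list:
    """The 16-row PWA clinical fixture; two records carry the MRS discard flag."""
    path = resources.files("gabasupp").joinpath("data/table1_pwa.csv")
    with resources.as_file(path) as p:
        frame = pd.read_csv(p)
    records = frame_to_records(frame)
    if len(records) != 16:
        raise RuntimeError(f"clinical fixture corrupt: {len(records)} rows, expected 16")
    flagged = {r.subject_id for r in records if r.mrs_quality_flag}
    if flagged != {"A5", "A10"}:
        raise RuntimeError(f"clinical fixture corrupt: MRS flags on {sorted(flagged)}")
    return records


# ---------------------------------------------------------------------------
# Synthetic MEGA-PRESS scans
# ---------------------------------------------------------------------------

#: (ppm, amplitude relative to Cr, Gaussian linewidth in Hz) spectral model.
#: Gaussian line shapes emulate shim-dominated in-vivo linewidths and keep
#: tail leakage outside the fixed integration windows negligible.  Cr and the
#: bystander lines appear in both edit states (and so cancel in the
#: difference spectrum); the GABA pseudo-doublet straddling 3.00 ppm appears
#: only in On-edited blocks and survives the subtraction.
_CR_AMPLITUDE = 1.0
_BYSTANDER_LINES = (
    (3.00, _CR_AMPLITUDE, 6.0),    # creatine CH3
    (3.22, 0.6, 6.0),              # choline
    (2.01, 1.5, 7.0),              # NAA
    (4.70, 0.4, 30.0),             # residual water, broad
)
_GABA_COMPONENT_PPMS = (2.97, 3.03)   # pseudo-doublet, J ~ 7.3 Hz at 3 T
_GABA_LB_HZ = 6.0


def _line_fid(t, ppm, amplitude, lb_hz, f_tx_mhz=mrs.F_TX_MHZ,
              center_ppm=mrs.CENTER_PPM):
    f_hz = (ppm - center_ppm) * f_tx_mhz
    decay = np.exp(-((np.pi * lb_hz * t) ** 2) / (4.0 * math.log(2.0)))
    return amplitude * np.exp(2j * np.pi * f_hz * t) * decay


def _noiseless_block_fid(t, edit_state, gaba_amplitude):
    fid = np.zeros_like(t, dtype=complex)
    for ppm, amp, lb in _BYSTANDER_LINES:
        fid += _line_fid(t, ppm, amp, lb)
    if edit_state == "On" and gaba_amplitude > 0:
        for ppm in _GABA_COMPONENT_PPMS:
            fid += _line_fid(t, ppm, gaba_amplitude / 2.0, _GABA_LB_HZ)
    return fid


def synthesize_scan(true_gaba_cr: float, snr: float = 20.0, seed: int = 0,
                    scan_id: str = "scan", n_blocks: int = 16,
                    phase_jitter: float = 0.2, shift_jitter: float = 0.01,
                    ) -> mrs.EditedScan:
    """Synthesize one MEGA-PRESS scan: ``n_blocks`` On + ``n_blocks`` Off
    raw block spectra of 1,024 complex time-domain points.

    The GABA amplitude is set so the noiseless quantification chain
    (difference-spectrum GABA window over summed-spectrum Cr window) returns
    ``true_gaba_cr``.  ``snr`` is the amplitude SNR of the Cr peak in the
    preprocessed spectrum; pass ``numpy.inf`` for noise-free blocks.  Each
    On/Off pair shares a small random zero-order phase and frequency offset,
    which the creatine-referenced correction must undo.
    """
    if true_gaba_cr < 0:
        raise ValueError("true_gaba_cr must be non-negative")
    if not snr > 0:
        raise ValueError("snr must be positive")
    if true_gaba_cr >= 1.0:
        raise ValueError("true_gaba_cr must be below 1")
    rng = np.random.default_rng(seed)
    t = np.arange(mrs.N_RAW) * mrs.DWELL_S
    # The difference spectrum carries 1x GABA while the summed spectrum
    # carries 2x Cr plus the On-only GABA doublet, which lies inside the Cr
    # integration window; a_g = 2 Cr R / (1 - R) makes the window ratio equal
    # the planted value.
    gaba_amp = 2.0 * _CR_AMPLITUDE * true_gaba_cr / (1.0 - true_gaba_cr)

    if np.isinf(snr):
        sigma_t = 0.0
    else:
        window = mrs.apodization_window(mrs.N_RAW, mrs.DWELL_S)
        ref = mrs.preprocess(mrs.BlockSpectrum(
            values=_noiseless_block_fid(t, "Off", 0.0), edit_state="Off"))
        ppm = ref.ppm_axis
        cr_mask = np.abs(ppm - mrs.CR_PPM) <= 0.05
        h_cr = float(ref.values.real[cr_mask].max())
        sigma_t = h_cr / (snr * math.sqrt(float(np.sum(window ** 2))))

    on_blocks, off_blocks = [], []
    for b in range(n_blocks):
        phase = rng.uniform(-phase_jitter, phase_jitter)
        shift = rng.uniform(-shift_jitter, shift_jitter)
        corruption = np.exp(1j * phase + 2j * np.pi * shift * mrs.F_TX_MHZ * t)
        for state, bucket in (("Off", off_blocks), ("On", on_blocks)):
            fid = _noiseless_block_fid(t, state, gaba_amp) * corruption
            if sigma_t > 0:
                fid = fid + sigma_t * (rng.standard_normal(t.size)
                                       + 1j * rng.standard_normal(t.size))
            bucket.append(mrs.BlockSpectrum(values=fid, edit_state=state,
                                            scan_id=scan_id, block_index=b))
    return mrs.EditedScan(on_blocks=on_blocks, off_blocks=off_blocks,
                          scan_id=scan_id)


# ---------------------------------------------------------------------------
# Psychophysical sessions
# ---------------------------------------------------------------------------

def simulate_sessions(records, truth: GroundTruth, spec: CohortSpec,
                      config: StaircaseConfig | None = None,
                      n_staircases: int = 4,
                      subjects=None) -> pd.DataFrame:
    """Simulate every staircase of the factorial design as a trial log.

    For each subject: two baseline (no surround) cells, one per eye, plus the
    2 (eye) x 2 (configuration) x 2 (orientation) conditions at each of the
    subject's surround contrasts, with ``n_staircases`` staircases per cell.
    The generating threshold of a cell is baseline x suppression multiplier.
    """
    if n_staircases < 4:
        raise ValueError("the design requires at least 4 staircases per cell")
    rng = np.random.default_rng(spec.seed + 7)
    chosen = {r.subject_id for r in records} if subjects is None else set(subjects)
    frames = []
    for rec in records:
        sid = rec.subject_id
        if sid not in chosen:
            continue
        cells = [(eye, "baseline", "none", None) for eye in EYES]
        for eye in EYES:
            for cfg in CONFIGS:
                for ori in ORIENTATIONS:
                    for c in truth.surround_contrasts[sid]:
                        cells.append((eye, cfg, ori, c))
        for eye, cfg, ori, c in cells:
            if cfg == "baseline":
                alpha = truth.baseline.get((sid, eye))
                if alpha is None:
                    raise KeyError(f"ground truth missing baseline cell ({sid}, {eye})")
            else:
                key = (sid, eye, cfg, ori, c)
                if key not in truth.multiplier:
                    raise KeyError(f"ground truth missing cell {key}")
                alpha = truth.baseline[(sid, eye)] * truth.multiplier[key]
            observer = WeibullObserver(alpha=alpha, beta=spec.observer_slope,
                                       lapse=spec.observer_lapse)
            base = config or StaircaseConfig()
            start = float(np.clip(10.0 * alpha, 2.0 * base.floor, base.ceiling))
            cell_config = StaircaseConfig(
                step=base.step, n_up=base.n_up, n_down=base.n_down,
                stop_reversals=base.stop_reversals,
                threshold_reversals=base.threshold_reversals,
                start_increment=start, max_trials=base.max_trials,
                floor=base.floor, ceiling=base.ceiling)
            cell_fields = {"subject_id": sid, "eye": eye, "ocular_config": cfg,
                           "orientation": ori,
                           "surround_contrast": np.nan if c is None else c}
            for k in range(n_staircases):
                trials, _ = run_staircase(
                    observer, cell_config,
                    seed=int(rng.integers(2 ** 31)),
                    cell=cell_fields, staircase_id=f"sc{k}")
                frames.append(trials)
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]
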
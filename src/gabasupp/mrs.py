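"""GABA:Cr quantification from MEGA-PRESS edited block spectra.

The editing sequence alternates On-resonance (1.9 ppm) and Off-resonance
(7.5 ppm) editing pulses.  Sets of 10 consecutive transients are averaged into
"block" spectra; a scan consists of 16 On and 16 Off blocks of 1,024 complex
time-domain points each.  Quantification proceeds through

1. preprocessing (4-Hz Gaussian apodization, zero-padding 1,024 -> 4,096,
   Fourier transform),
2. creatine-referenced phase and frequency correction estimated on each Off
   block and applied identically to its paired On block,
3. automated quality control (per-frequency deviant tally across blocks),
4. averaging into the On-Off difference spectrum (edited GABA) and the On+Off
   summed spectrum (creatine), and
5. real-part trapezoidal peak integration: GABA over 2.85-3.15 ppm in the
   difference spectrum, creatine over 2.93-3.10 ppm in the summed spectrum.

GABA:Cr is the ratio of the two integrals; per subject it is the mean over
that subject's retained scans.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

# Acquisition constants (3 T MEGA-PRESS)
N_RAW = 1024
N_PROC = 4096
DWELL_S = 4.0e-4          # 2500 Hz spectral width
F_TX_MHZ = 123.23         # proton transmit frequency at 3 T
CENTER_PPM = 4.7          # carrier on water

# Quantification windows (ppm)
GABA_WINDOW = (2.85, 3.15)
CR_WINDOW = (2.93, 3.10)
CR_PPM = 3.00
CR_SEARCH_HALFWIDTH = 0.15
APOD_LB_HZ = 4.0

DEFAULT_METADATA = {
    "tr_ms": 1500.0,
    "te_ms": 68.0,
    "edit_on_ppm": 1.9,
    "edit_off_ppm": 7.5,
    "f_tx_mhz": F_TX_MHZ,
    "dwell_s": DWELL_S,
}


class RdaParseError(ValueError):
    """Malformed rda-dialect block file; message names the offending field."""


class InvalidBlockError(ValueError):
    pass


class PairingError(ValueError):
    pass


class UncorrectableBlockError(RuntimeError):
    """No usable creatine peak in the search window."""


class QcError(RuntimeError):
    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class QuantificationError(RuntimeError):
    pass


@dataclass
class BlockSpectrum:
    """One 10-transient average, in the time domain (raw) or frequency domain.

    Frequency-domain values are stored with the ppm axis strictly decreasing
    (index 0 = highest ppm), the conventional left-to-right display order.
    """

    values: np.ndarray
    edit_state: str                 # "On" | "Off" (averages may use "Diff"/"Sum")
    scan_id: str = "scan"
    block_index: int = 0
    domain: str = "time"            # "time" | "freq"
    dwell_s: float = DWELL_S
    f_tx_mhz: float = F_TX_MHZ
    center_ppm: float = CENTER_PPM
    phase_applied: float = 0.0      # radians
    shift_applied: float = 0.0      # ppm

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 1:
            raise InvalidBlockError("values must be a 1-D complex array")
        if self.domain not in ("time", "freq"):
            raise InvalidBlockError(f"unknown domain {self.domain!r}")
        if self.edit_state not in ("On", "Off", "Diff", "Sum"):
            raise InvalidBlockError(f"unknown edit_state {self.edit_state!r}")

    @property
    def n_points(self) -> int:
        return self.values.size

    @property
    def ppm_axis(self) -> np.ndarray:
        """Chemical-shift axis (ppm), strictly decreasing. Frequency domain only."""
        if self.domain != "freq":
            raise InvalidBlockError("ppm_axis is defined for frequency-domain blocks")
        return _ppm_axis(self.n_points, self.dwell_s, self.f_tx_mhz, self.center_ppm)

    @property
    def key(self):
        return (self.edit_state, self.block_index)


def _ppm_axis(n, dwell_s, f_tx_mhz, center_ppm):
    f_asc = np.fft.fftshift(np.fft.fftfreq(n, d=dwell_s))
    return (center_ppm + f_asc / f_tx_mhz)[::-1]


def _fid_to_spectrum(fid, n_out):
    """FFT with the descending-ppm storage convention."""
    return np.fft.fftshift(np.fft.fft(fid, n_out))[::-1]


def _spectrum_to_fid(values_desc):
    return np.fft.ifft(np.fft.ifftshift(values_desc[::-1]))


@dataclass
class EditedScan:
    """Paired On/Off block spectra for one MEGA-PRESS scan."""

    on_blocks: list
    off_blocks: list
    scan_id: str = "scan"
    metadata: dict = field(default_factory=lambda: dict(DEFAULT_METADATA))

    def __post_init__(self):
        if len(self.on_blocks) != len(self.off_blocks):
            raise InvalidBlockError(
                f"unequal block counts: {len(self.on_blocks)} On vs "
                f"{len(self.off_blocks)} Off"
            )

    @property
    def blocks(self):
        return list(self.on_blocks) + list(self.off_blocks)


@dataclass
class QcReport:
    deviant_counts: dict            # (edit_state, block_index) -> count
    excluded: list                  # keys of excluded blocks
    exclusion_fraction: float
    max_deviant: int

    def __post_init__(self):
        if not 0.0 <= self.exclusion_fraction <= 1.0:
            raise ValueError("exclusion_fraction outside [0, 1]")


@dataclass
class MetaboliteEstimate:
    gaba_area: float
    cr_area: float
    gaba_cr: float
    n_blocks_used: int
    qc: QcReport | None = None


# ---------------------------------------------------------------------------
# rda-dialect IO
# ---------------------------------------------------------------------------

_HEADER_END = ">>> End of header <<<"
_HEADER_FIELDS = ("VectorSize", "TransmitFrequency", "DwellTime", "CenterPpm",
                  "EditState", "ScanId", "BlockIndex")


def _block_filename(block: BlockSpectrum) -> str:
    return f"{block.scan_id}_{block.edit_state}_{block.block_index:02d}.rda"


def write_rda_block(block: BlockSpectrum, path: str) -> None:
    if block.domain != "time":
        raise InvalidBlockError("rda files store raw time-domain blocks")
    lines = [
        f"VectorSize: {block.n_points}",
        f"TransmitFrequency: {block.f_tx_mhz:.6f}",
        f"DwellTime: {block.dwell_s * 1e6:.3f}",
        f"CenterPpm: {block.center_ppm:.6f}",
        f"EditState: {block.edit_state}",
        f"ScanId: {block.scan_id}",
        f"BlockIndex: {block.block_index}",
        _HEADER_END,
    ]
    body = "\n".join(f"{v.real:.17g} {v.imag:.17g}" for v in block.values)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n" + body + "\n")


def read_rda_block(path: str) -> BlockSpectrum:
    with open(path) as fh:
        text = fh.read()
    if _HEADER_END not in text:
        raise RdaParseError(f"{path}: missing header terminator {_HEADER_END!r}")
    head, body = text.split(_HEADER_END, 1)
    fields = {}
    for line in head.splitlines():
        line = line.strip()
        if not line:
            continue
        if ":" not in line:
            raise RdaParseError(f"{path}: malformed header line {line!r}")
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()
    for required in ("VectorSize", "EditState"):
        if required not in fields:
            raise RdaParseError(f"{path}: missing header field {required!r}")
    if fields["EditState"] not in ("On", "Off"):
        raise RdaParseError(f"{path}: bad EditState {fields['EditState']!r}")
    n = int(fields["VectorSize"])
    raw = body.split()
    if len(raw) != 2 * n:
        raise RdaParseError(
            f"{path}: VectorSize {n} but {len(raw) // 2} complex pairs found"
        )
    arr = np.array(raw, dtype=float).reshape(n, 2)
    return BlockSpectrum(
        values=arr[:, 0] + 1j * arr[:, 1],
        edit_state=fields["EditState"],
        scan_id=fields.get("ScanId", "scan"),
        block_index=int(fields.get("BlockIndex", 0)),
        domain="time",
        dwell_s=float(fields.get("DwellTime", DWELL_S * 1e6)) * 1e-6,
        f_tx_mhz=float(fields.get("TransmitFrequency", F_TX_MHZ)),
        center_ppm=float(fields.get("CenterPpm", CENTER_PPM)),
    )


def write_rda_bundle(scan: EditedScan, directory: str) -> str:
    """Write one rda file per block plus a JSON manifest; returns manifest path."""
    os.makedirs(directory, exist_ok=True)
    files = []
    for block in scan.blocks:
        name = _block_filename(block)
        write_rda_block(block, os.path.join(directory, name))
        files.append(name)
    manifest = {
        "scan_id": scan.scan_id,
        "metadata": scan.metadata,
        "files": files,
    }
    mpath = os.path.join(directory, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return mpath


def read_rda_bundle(directory: str) -> EditedScan:
    mpath = os.path.join(directory, "manifest.json")
    if not os.path.exists(mpath):
        raise RdaParseError(f"{directory}: missing manifest.json")
    with open(mpath) as fh:
        manifest = json.load(fh)
    on, off = [], []
    for name in manifest["files"]:
        block = read_rda_block(os.path.join(directory, name))
        (on if block.edit_state == "On" else off).append(block)
    on.sort(key=lambda b: b.block_index)
    off.sort(key=lambda b: b.block_index)
    return EditedScan(on_blocks=on, off_blocks=off,
                      scan_id=manifest.get("scan_id", "scan"),
                      metadata=manifest.get("metadata", dict(DEFAULT_METADATA)))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def apodization_window(n: int, dwell_s: float, lb_hz: float = APOD_LB_HZ) -> np.ndarray:
    """Time-domain Gaussian window adding ``lb_hz`` of Gaussian FWHM.

    w(t) = exp(-(pi * LB * t)^2 / (4 ln 2)) convolves the spectrum with a
    Gaussian of FWHM = LB hertz.
    """
    t = np.arange(n) * dwell_s
    return np.exp(-((np.pi * lb_hz * t) ** 2) / (4.0 * math.log(2.0)))


def preprocess(block: BlockSpectrum) -> BlockSpectrum:
    """Apodize (4-Hz Gaussian), zero-pad 1,024 -> 4,096, Fourier transform."""
    if block.domain != "time" or block.n_points != N_RAW:
        raise InvalidBlockError(
            f"preprocess expects a raw {N_RAW}-point time-domain block, got "
            f"{block.n_points} points in {block.domain!r} domain"
        )
    fid = block.values * apodization_window(block.n_points, block.dwell_s)
    spectrum = _fid_to_spectrum(fid, N_PROC)
    return replace(block, values=spectrum, domain="freq")


def apply_phase_shift(block: BlockSpectrum, phase: float, shift_ppm: float) -> BlockSpectrum:
    """Multiply by exp(i*phase) and translate features by +shift_ppm.

    Exact (sub-bin) translation via time-domain modulation.
    """
    if block.domain != "freq":
        raise InvalidBlockError("apply_phase_shift expects a frequency-domain block")
    fid = _spectrum_to_fid(block.values)
    t = np.arange(block.n_points) * block.dwell_s
    fid = fid * np.exp(1j * phase + 2j * np.pi * shift_ppm * block.f_tx_mhz * t)
    return replace(
        block,
        values=_fid_to_spectrum(fid, block.n_points),
        phase_applied=block.phase_applied + phase,
        shift_applied=block.shift_applied + shift_ppm,
    )


# ---------------------------------------------------------------------------
# Creatine-referenced correction
# ---------------------------------------------------------------------------

def _parabolic_vertex(y0, y1, y2):
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return 0.0
    return 0.5 * (y0 - y2) / denom


def phase_and_frequency_correct(off: BlockSpectrum,
                                reference_ppm: float = CR_PPM,
                                halfwidth_ppm: float = CR_SEARCH_HALFWIDTH,
                                ) -> tuple[float, float]:
    """Estimate (phase, shift) of the creatine line on an Off block.

    Returns the corruption parameters: the Cr peak sits at
    ``reference_ppm + shift`` with complex phase ``phase``.  Undo them with
    ``apply_phase_shift(block, -phase, -shift)``, which maximizes the real Cr
    height and recenters it at the reference within one bin.
    """
    if off.domain != "freq":
        raise InvalidBlockError("correction expects a preprocessed block")
    ppm = off.ppm_axis
    mask = np.abs(ppm - reference_ppm) <= halfwidth_ppm
    idx = np.flatnonzero(mask)
    window = off.values[idx]
    mag = np.abs(window)
    j = int(np.argmax(mag))
    # Degenerate inputs: peak on the window edge, or not prominent above the
    # spectrum-wide noise floor.
    floor = np.median(np.abs(off.values))
    if j in (0, mag.size - 1) or (floor > 0 and mag[j] < 4.0 * floor):
        raise UncorrectableBlockError(
            f"no usable Cr peak near {reference_ppm} ppm in block "
            f"{off.key} of scan {off.scan_id}"
        )
    # Sub-bin peak position from a parabola through the magnitude triplet.
    delta = _parabolic_vertex(mag[j - 1], mag[j], mag[j + 1])
    delta = float(np.clip(delta, -0.5, 0.5))
    i = idx[j]
    bin_step = ppm[min(i + 1, ppm.size - 1)] - ppm[i]  # negative (descending axis)
    peak_ppm = ppm[i] + delta * bin_step
    shift = float(peak_ppm - reference_ppm)
    # Phase from a matched-filter average over the line core: deterministic
    # Gaussian template weights centered on the refined peak, so the noise of
    # ~20 bins is averaged down and the dispersion wings of a symmetric line
    # cancel, rather than trusting a single noisy bin.
    sigma_ppm = 3.0 / off.f_tx_mhz        # ~ line-core width at 3 T
    w = np.exp(-0.5 * ((ppm - peak_ppm) / sigma_ppm) ** 2)
    w[np.abs(ppm - peak_ppm) > 4 * sigma_ppm] = 0.0
    phase = float(np.angle(np.sum(w * off.values)))
    return phase, shift


def apply_pair_correction(on: BlockSpectrum, phase: float, shift: float,
                          off: BlockSpectrum | None = None) -> BlockSpectrum:
    """Apply the Off-derived correction to the paired On block.

    If the corrected Off block is supplied, the pairing (same block_index) is
    verified first.
    """
    if off is not None and off.block_index != on.block_index:
        raise PairingError(
            f"On block {on.block_index} paired with Off block {off.block_index}"
        )
    return apply_phase_shift(on, -phase, -shift)


def correct_scan(scan: EditedScan) -> tuple[EditedScan, dict]:
    """Estimate Cr phase/shift on each Off block; apply to it and its pair.

    Blocks whose Off partner is uncorrectable are dropped from both states.
    Returns the corrected scan and a table of per-pair corrections.
    """
    corrections = {}
    on_out, off_out = [], []
    off_by_index = {b.block_index: b for b in scan.off_blocks}
    for on in scan.on_blocks:
        off = off_by_index.get(on.block_index)
        if off is None:
            raise PairingError(f"On block {on.block_index} has no Off partner")
        try:
            phase, shift = phase_and_frequency_correct(off)
        except UncorrectableBlockError:
            corrections[on.block_index] = None
            continue
        corrections[on.block_index] = (phase, shift)
        off_out.append(apply_phase_shift(off, -phase, -shift))
        on_out.append(apply_pair_correction(on, phase, shift, off=off))
    if not on_out:
        raise QuantificationError(f"scan {scan.scan_id}: no correctable block pairs")
    return EditedScan(on_blocks=on_out, off_blocks=off_out,
                      scan_id=scan.scan_id, metadata=scan.metadata), corrections


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_blocks(scan: EditedScan, max_deviant: int = 300) -> QcReport:
    """Tally per-frequency deviants (> 2 SD across same-state blocks).

    A block whose deviant count exceeds ``max_deviant`` is excluded.  QC is
    exclusion-only: retained blocks are never modified.
    """
    counts, excluded = {}, []
    for blocks in (scan.on_blocks, scan.off_blocks):
        if len(blocks) < 3:
            raise QcError("need at least 3 blocks per edit state for QC")
        x = np.vstack([b.values.real for b in blocks])
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        # absolute floor guards against float rounding in near-zero bins,
        # where the across-block variance underflows
        tol = 1e-12 * np.abs(x).max()
        dev = np.abs(x - mean) > 2.0 * sd + tol
        for b, row in zip(blocks, dev):
            n_dev = int(row.sum())
            counts[b.key] = n_dev
            if n_dev > max_deviant:
                excluded.append(b.key)
    report = QcReport(deviant_counts=counts, excluded=excluded,
                      exclusion_fraction=len(excluded) / len(counts),
                      max_deviant=max_deviant)
    retained_states = {key[0] for key in counts if key not in excluded}
    if retained_states != {"On", "Off"}:
        raise QcError("all blocks of an edit state excluded by QC", report=report)
    return report


# ---------------------------------------------------------------------------
# Averaging and integration
# ---------------------------------------------------------------------------

def difference_and_sum(scan: EditedScan, excluded=()) -> tuple[BlockSpectrum, BlockSpectrum]:
    """diff = mean(On) - mean(Off); summed = mean(On) + mean(Off).

    Only retained (non-excluded) blocks enter the averages.
    """
    excluded = set(excluded)
    on = [b for b in scan.on_blocks if b.key not in excluded]
    off = [b for b in scan.off_blocks if b.key not in excluded]
    if not on or not off:
        raise QuantificationError("no retained blocks in one edit state")
    mean_on = np.mean([b.values for b in on], axis=0)
    mean_off = np.mean([b.values for b in off], axis=0)
    template = on[0]
    diff = replace(template, values=mean_on - mean_off, edit_state="Diff", block_index=-1)
    summed = replace(template, values=mean_on + mean_off, edit_state="Sum", block_index=-1)
    return diff, summed


def integrate_peak(spectrum: BlockSpectrum, ppm_lo: float, ppm_hi: float,
                   baseline_correction: bool = False) -> float:
    """Trapezoidal integral of the real part over the closed window [lo, hi].

    Bin membership is by bin center.  With ``baseline_correction`` a straight
    line through the window endpoints is subtracted first (default off).
    """
    if not ppm_lo < ppm_hi:
        raise ValueError(f"ppm window reversed: [{ppm_lo}, {ppm_hi}]")
    ppm = spectrum.ppm_axis
    if ppm_lo < ppm.min() or ppm_hi > ppm.max():
        raise ValueError(f"ppm window [{ppm_lo}, {ppm_hi}] outside axis range")
    mask = (ppm >= ppm_lo) & (ppm <= ppm_hi)
    x = ppm[mask][::-1]                      # ascending ppm
    y = spectrum.values.real[mask][::-1]
    if baseline_correction and x.size >= 2:
        y = y - np.interp(x, [x[0], x[-1]], [y[0], y[-1]])
    return float(np.trapezoid(y, x))


def gaba_cr_ratio(scan: EditedScan, max_deviant: int = 300,
                  baseline_correction: bool = False,
                  preprocessed: bool = False) -> MetaboliteEstimate:
    """Full quantification chain for one scan.

    preprocess -> Cr-referenced correction -> QC -> difference/sum ->
    windowed integration -> GABA:Cr.
    """
    if not preprocessed:
        scan = EditedScan(
            on_blocks=[preprocess(b) for b in scan.on_blocks],
            off_blocks=[preprocess(b) for b in scan.off_blocks],
            scan_id=scan.scan_id, metadata=scan.metadata)
    scan, _ = correct_scan(scan)
    report = qc_blocks(scan, max_deviant=max_deviant)
    diff, summed = difference_and_sum(scan, excluded=report.excluded)
    gaba_area = integrate_peak(diff, *GABA_WINDOW, baseline_correction=baseline_correction)
    cr_area = integrate_peak(summed, *CR_WINDOW, baseline_correction=baseline_correction)
    if cr_area <= 0:
        raise QuantificationError(
            f"scan {scan.scan_id}: non-positive creatine area {cr_area:g}")
    n_used = len(report.deviant_counts) - len(report.excluded)
    return MetaboliteEstimate(gaba_area=gaba_area, cr_area=cr_area,
                              gaba_cr=gaba_area / cr_area,
                              n_blocks_used=n_used, qc=report)


def quantify_subject(scans, **kwargs) -> MetaboliteEstimate:
    """Per-subject GABA:Cr: mean over the subject's retained scans.

    Scans acquired under different visual-stimulation conditions are averaged;
    scans failing quantification are dropped.
    """
    estimates = []
    for scan in scans:
        try:
            estimates.append(gaba_cr_ratio(scan, **kwargs))
        except (QcError, QuantificationError):
            continue
    if not estimates:
        raise QuantificationError("no scan survived quantification")
    return MetaboliteEstimate(
        gaba_area=float(np.mean([e.gaba_area for e in estimates])),
        cr_area=float(np.mean([e.cr_area for e in estimates])),
        gaba_cr=float(np.mean([e.gaba_cr for e in estimates])),
        n_blocks_used=int(np.sum([e.n_blocks_used for e in estimates])),
    )
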
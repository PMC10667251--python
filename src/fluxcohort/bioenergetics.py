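"""Mitochondrial stress-test trace reduction and ATP-rate bookkeeping.

A trace is an ordered series of OCR (pmol O2/min) and ECAR (mpH/min)
measurements per well with an injection schedule: port A = oligomycin (ATP
synthase inhibitor), B = FCCP (uncoupler), C = rotenone/antimycin A (electron
transport shutdown), D = 2-deoxyglucose (glycolysis shutdown).  Segment means
reduce the trace to basal, proton-leak and maximal respiration after
subtracting non-mitochondrial OCR (mean of the last two points after port C;
cell types measured with a single terminal point use the last point only),
and the mitochondrial ATP production rate follows from the oxygen deficit:

    mitoATP rate = (OCR_basal - OCR_proton_leak) * 2 (pmol O/pmol O2) * P/O

with a default P/O ratio of 2.75 pmol ATP/pmol O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InjectionSchedule",
    "SeahorseTrace",
    "BioenergeticParams",
    "reduce_seahorse_trace",
    "mito_atp_rate",
    "ecar_ocr_ratio",
    "dna_standard_curve",
    "P_TO_O_RATIO",
]

P_TO_O_RATIO = 2.75


@dataclass(frozen=True)
class InjectionSchedule:
    """Counts of measuring points per segment: basal then after ports A-D."""

    n_basal: int = 4
    n_post_a: int = 3
    n_post_b: int = 3
    n_post_c: int = 3
    n_post_d: int = 3

    @property
    def n_points(self) -> int:
        return self.n_basal + self.n_post_a + self.n_post_b + self.n_post_c + self.n_post_d

    def segments(self) -> dict[str, slice]:
        i0 = 0
        out = {}
        for name, n in (
            ("basal", self.n_basal),
            ("post_a", self.n_post_a),
            ("post_b", self.n_post_b),
            ("post_c", self.n_post_c),
            ("post_d", self.n_post_d),
        ):
            out[name] = slice(i0, i0 + n)
            i0 += n
        return out


@dataclass
class SeahorseTrace:
    ocr: np.ndarray  # pmol O2/min, raw per measuring point
    ecar: np.ndarray  # mpH/min
    schedule: InjectionSchedule
    dna_mg: float = 1.0
    celltype: str = "hNPC"  # hNPC/hiPSC use 2 terminal points, DAn uses 1
    keys: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ocr = np.asarray(self.ocr, dtype=float)
        self.ecar = np.asarray(self.ecar, dtype=float)
        if len(self.ocr) != self.schedule.n_points:
            raise ValueError(
                f"trace has {len(self.ocr)} points, schedule expects "
                f"{self.schedule.n_points}"
            )
        n_term = 1 if self.celltype == "DAn" else 2
        if self.schedule.n_post_c < n_term:
            raise ValueError("schedule lacks the terminal points after port C")


@dataclass
class BioenergeticParams:
    """DNA-normalized respiratory/glycolytic parameters.

    OCRs are corrected (non-mitochondrial subtracted); ECARs analogously
    (non-glycolytic subtracted).  ``atp_linked = basal - proton_leak``.
    """

    ocr_basal: float
    ocr_proton_leak: float
    ocr_maximal: float
    ocr_nonmito: float
    ecar_basal: float
    ecar_max: float
    ecar_nonglyc: float
    dna_mg: float = 1.0
    qc_flag: str | None = None

    @property
    def ocr_atp_linked(self) -> float:
        return self.ocr_basal - self.ocr_proton_leak

    @property
    def mito_atp(self) -> float:
        return mito_atp_rate(self)


def reduce_seahorse_trace(trace: SeahorseTrace) -> BioenergeticParams:
    """Segment means -> bioenergetic parameters, normalized per mg DNA.

    basal uses the points prior to port A; proton leak the points after A and
    prior to B; maximal the points after B and prior to C.  Negative corrected
    basal respiration is flagged, not clipped, so cohort statistics see the
    raw estimate.
    """
    seg = trace.schedule.segments()
    n_term = 1 if trace.celltype == "DAn" else 2
    ocr = trace.ocr
    ecar = trace.ecar
    nonmito = float(np.mean(ocr[seg["post_c"]][-n_term:]))
    nonglyc = float(np.mean(ecar[seg["post_d"]][-n_term:]))
    basal = float(np.mean(ocr[seg["basal"]])) - nonmito
    leak = float(np.mean(ocr[seg["post_a"]])) - nonmito
    maximal = float(np.mean(ocr[seg["post_b"]])) - nonmito
    ecar_basal = float(np.mean(ecar[seg["basal"]])) - nonglyc
    ecar_max = float(np.mean(ecar[seg["post_a"]])) - nonglyc
    # simple per-well QC: non-mitochondrial OCR exceeding the basal segment
    flag = "negative_corrected_basal" if basal < 0 else None
    d = trace.dna_mg
    if d <= 0:
        raise ValueError("DNA content must be positive")
    return BioenergeticParams(
        ocr_basal=basal / d,
        ocr_proton_leak=leak / d,
        ocr_maximal=maximal / d,
        ocr_nonmito=nonmito / d,
        ecar_basal=ecar_basal / d,
        ecar_max=ecar_max / d,
        ecar_nonglyc=nonglyc / d,
        dna_mg=d,
        qc_flag=flag,
    )


def mito_atp_rate(params: BioenergeticParams, p_to_o: float = P_TO_O_RATIO) -> float:
    """(basal - proton leak) * 2 pmol O / pmol O2 * P/O, in pmol ATP/min."""
    return (params.ocr_basal - params.ocr_proton_leak) * 2.0 * p_to_o


def ecar_ocr_ratio(params: BioenergeticParams) -> float:
    """Basal ECAR over basal OCR; NaN when basal OCR is zero (undefined)."""
    if params.ocr_basal == 0:
        return float("nan")
    return params.ecar_basal / params.ocr_basal


def dna_standard_curve(standards) -> dict:
    """OLS line through (DNA mass, fluorescence) standards.

    Returns slope/intercept plus a ``quantify`` callable inverting the line;
    quantified samples outside the standard range carry an extrapolation flag.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (mass, fluorescence) standards")
    mass, fluo = arr[:, 0], arr[:, 1]
    if np.ptp(mass) == 0:
        raise ValueError("standards have zero variance in mass")
    slope, intercept = np.polyfit(mass, fluo, 1)
    lo, hi = fluo.min(), fluo.max()

    def quantify(f: float) -> tuple[float, bool]:
        extrapolated = not (lo <= f <= hi)
        return (f - intercept) / slope, extrapolated

    return {"slope": float(slope), "intercept": float(intercept), "quantify": quantify}
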
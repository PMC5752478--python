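"""Functional-assay arithmetic: mito-stress-test OCR decomposition and
2^-ddCt relative quantification.

The mito stress test injects oligomycin (blocks ATP synthase), FCCP
(uncouples, driving maximal respiration) and rotenone/antimycin A (shuts
down the electron transport chain). Each phase plateau is summarized and
the standard respiratory parameters follow by subtraction:

    non_mito    = post-Rot/AA plateau
    basal_mito  = baseline - non_mito
    atp_linked  = baseline - post-oligo
    proton_leak = post-oligo - non_mito
    maximal     = post-FCCP - non_mito
    spare       = maximal - basal_mito

so that atp_linked + proton_leak == basal_mito holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TriomixError


@dataclass
class MitoStressTrace:
    """One well's OCR time series with injection annotations.

    ``oligomycin_idx``/``fccp_idx``/``rotenone_idx`` are the indices of the
    first measurement AFTER the respective injection; they must be strictly
    increasing and leave >= 2 measurements in every phase.
    """

    time: np.ndarray
    ocr: np.ndarray
    oligomycin_idx: int
    fccp_idx: int
    rotenone_idx: int
    ecar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.ocr = np.asarray(self.ocr, float)
        if self.time.shape != self.ocr.shape:
            raise TriomixError("time and OCR must have equal length")
        idx = (self.oligomycin_idx, self.fccp_idx, self.rotenone_idx)
        if any(i is None for i in idx):
            raise TriomixError("all three injection indices must be annotated")
        if not (0 < idx[0] < idx[1] < idx[2] < len(self.ocr)):
            raise TriomixError("injection indices must be strictly increasing and in range")
        for lo, hi in zip((0,) + idx, idx + (len(self.ocr),)):
            if hi - lo < 2:
                raise TriomixError("every phase needs >= 2 measurements")

    def phases(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        i, j, k = self.oligomycin_idx, self.fccp_idx, self.rotenone_idx
        return self.ocr[:i], self.ocr[i:j], self.ocr[j:k], self.ocr[k:]


@dataclass
class MitoStressProfile:
    basal_mito: float
    atp_linked: float
    proton_leak: float
    non_mito: float
    maximal: float
    spare_capacity: float
    basal_ecar: float | None = None
    qc_warning: bool = False

    def as_dict(self) -> dict:
        return {
            "basal_mito": self.basal_mito,
            "atp_linked": self.atp_linked,
            "proton_leak": self.proton_leak,
            "non_mito": self.non_mito,
            "maximal": self.maximal,
            "spare_capacity": self.spare_capacity,
        }


def mito_stress_params(trace: MitoStressTrace) -> MitoStressProfile:
    """Decompose an OCR trace into the standard respiratory parameters.

    Phase summaries follow the usual reporting convention: baseline = mean
    of its last three measurements, post-oligomycin = phase minimum,
    post-FCCP = phase maximum, post-Rot/AA = phase minimum. Negative
    derived rates are reported as-is with ``qc_warning`` set rather than
    clipped.
    """
    base, oligo, fccp, rot = trace.phases()
    baseline = float(np.mean(base[-3:]))
    post_oligo = float(np.min(oligo))
    post_fccp = float(np.max(fccp))
    non_mito = float(np.min(rot))
    basal_mito = baseline - non_mito
    atp_linked = baseline - post_oligo
    proton_leak = post_oligo - non_mito
    maximal = post_fccp - non_mito
    spare = maximal - basal_mito
    values = (basal_mito, atp_linked, proton_leak, non_mito, maximal, spare)
    basal_ecar = None
    if trace.ecar is not None:
        basal_ecar = float(np.mean(np.asarray(trace.ecar, float)[: trace.oligomycin_idx][-3:]))
    return MitoStressProfile(
        basal_mito=basal_mito,
        atp_linked=atp_linked,
        proton_leak=proton_leak,
        non_mito=non_mito,
        maximal=maximal,
        spare_capacity=spare,
        basal_ecar=basal_ecar,
        qc_warning=any(v < 0 for v in values),
    )


def read_mito_table(path) -> dict[tuple[str, str], MitoStressTrace]:
    """Read a long-format trace CSV (time, well, group, OCR[, ECAR], phase).

    ``phase`` must be one of baseline/oligomycin/fccp/rotenone; injection
    indices are derived from the phase boundaries. Returns
    {(group, well): trace}.
    """
    df = pd.read_csv(path)
    needed = {"time", "well", "group", "OCR", "phase"}
    if not needed <= set(df.columns):
        raise TriomixError(f"trace table needs columns {sorted(needed)}")
    order = {"baseline": 0, "oligomycin": 1, "fccp": 2, "rotenone": 3}
    traces = {}
    for (group, well), sub in df.groupby(["group", "well"], sort=True):
        sub = sub.sort_values("time", kind="mergesort")
        codes = sub["phase"].map(order)
        if codes.isna().any():
            raise TriomixError(f"unknown phase label in well {well!r}")
        codes = codes.to_numpy()
        if np.any(np.diff(codes) < 0):
            raise TriomixError(f"phases out of order in well {well!r}")
        idx = [int(np.searchsorted(codes, k)) for k in (1, 2, 3)]
        traces[(str(group), str(well))] = MitoStressTrace(
            time=sub["time"].to_numpy(),
            ocr=sub["OCR"].to_numpy(),
            oligomycin_idx=idx[0],
            fccp_idx=idx[1],
            rotenone_idx=idx[2],
            ecar=sub["ECAR"].to_numpy() if "ECAR" in sub else None,
        )
    return traces


# ---------------------------------------------------------------------------
# 2^-ddCt
# ---------------------------------------------------------------------------

def ddct(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_samples: set[str] | list[str],
) -> pd.DataFrame:
    """Relative quantification by the 2^-ddCt method.

    ``table`` has columns (sample_id, gene, ct). For each non-reference
    gene and sample, dCt = Ct_gene - Ct_ref(sample); ddCt subtracts the
    calibrator-group mean dCt (computed on the dCt scale); RQ = 2^-ddCt.
    """
    needed = {"sample_id", "gene", "ct"}
    if not needed <= set(table.columns):
        raise TriomixError(f"Ct table needs columns {sorted(needed)}")
    if (table["ct"] <= 0).any():
        raise TriomixError("Ct values must be positive")
    calibrator = set(calibrator_samples)
    if not calibrator:
        raise TriomixError("calibrator group is empty")
    wide = table.pivot_table(index="sample_id", columns="gene", values="ct", aggfunc="mean")
    if reference_gene not in wide.columns:
        raise TriomixError(f"reference gene {reference_gene!r} absent from the table")
    if wide[reference_gene].isna().any():
        bad = wide.index[wide[reference_gene].isna()][0]
        raise TriomixError(f"sample {bad!r} lacks a reference-gene Ct")
    missing_cal = calibrator - set(wide.index)
    if missing_cal:
        raise TriomixError(f"calibrator samples absent from the table: {sorted(missing_cal)}")
    rows = []
    for gene in wide.columns:
        if gene == reference_gene:
            continue
        dct = wide[gene] - wide[reference_gene]
        cal_mean = float(dct.loc[sorted(calibrator)].mean())
        for sample in wide.index:
            if np.isnan(wide.at[sample, gene]):
                continue
            ddct_val = float(dct[sample] - cal_mean)
            rows.append(
                {"sample_id": sample, "gene": gene, "delta_ct": float(dct[sample]),
                 "ddct": ddct_val, "rq": float(2.0 ** (-ddct_val))}
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "delta_ct", "ddct", "rq"])
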
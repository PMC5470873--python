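"""On-disk formats: sweep CSV + JSON sidecar, tidy I-V tables, fit results.

Sweep data use a long-format CSV (patch_id, calcium_mM, sweep_index,
time_ms, voltage_mV, current_pA) with a JSON sidecar holding the protocol,
condition, seeds and — for synthetic data — the generating ground truth.
No binary acquisition formats are read; an importer for those is an
extension point.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .barrier import BarrierModelParams
from .fitting import FitResult
from .ivcurve import IVCurve, Normalization
from .simulate import PatchPair, PatchRecording, StepProtocol, Sweep
from .thermo import IonSpec, Thermo

SWEEP_COLUMNS = [
    "patch_id",
    "calcium_mM",
    "sweep_index",
    "time_ms",
    "voltage_mV",
    "current_pA",
]


class SweepFormatError(ValueError):
    """Malformed sweep file; the message names the offending CSV line."""


def _recording_frame(rec: PatchRecording) -> pd.DataFrame:
    t = rec.protocol.time_base_ms()
    frames = []
    for s in rec.sweeps:
        frames.append(
            pd.DataFrame(
                {
                    "patch_id": rec.patch_id,
                    "calcium_mM": rec.calcium_mM,
                    "sweep_index": s.sweep_index,
                    "time_ms": t,
                    "voltage_mV": s.command_mV,
                    "current_pA": s.current_pA,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_sweeps(
    pairs: Mapping[str, List[PatchPair]],
    csv_path: Path,
    sidecar_path: Optional[Path] = None,
) -> None:
    """Write a dataset of test+background recordings and its sidecar."""
    csv_path = Path(csv_path)
    frames = []
    sidecar: Dict = {"constructs": {}}
    first_proto: Optional[StepProtocol] = None
    for construct, plist in pairs.items():
        entries = []
        for pair in plist:
            for rec in (pair.test, pair.background):
                frames.append(_recording_frame(rec))
            if first_proto is None:
                first_proto = pair.test.protocol
            entries.append(
                {
                    "patch_id": pair.test.patch_id,
                    "voltage_offset_mV": pair.test.voltage_offset_mV,
                    "true_params": (
                        dataclasses.asdict(pair.test.true_params)
                        if pair.test.true_params
                        else None
                    ),
                    "ion": dataclasses.asdict(pair.test.ion),
                    "calcium_mM": pair.test.calcium_mM,
                }
            )
        sidecar["constructs"][construct] = entries
    if first_proto is None:
        raise ValueError("empty dataset")
    sidecar["protocol"] = dataclasses.asdict(first_proto)
    sidecar["thermo"] = dataclasses.asdict(next(iter(pairs.values()))[0].test.thermo)
    pd.concat(frames, ignore_index=True).to_csv(
        csv_path, index=False, float_format="%.9g"
    )
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_sweeps(
    csv_path: Path, sidecar_path: Optional[Path] = None
) -> Dict[str, List[PatchPair]]:
    """Read a sweep CSV + sidecar back into paired recordings.

    Schema violations raise :class:`SweepFormatError` naming the first
    offending line (1-based, header included).
    """
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    sidecar = json.loads(Path(sidecar_path).read_text())
    protocol = StepProtocol(**sidecar["protocol"])
    thermo = Thermo(**sidecar["thermo"])

    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SweepFormatError(f"cannot parse {csv_path}: {exc}") from exc
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise SweepFormatError(f"{csv_path}: missing columns {missing} (line 1)")
    for col in ("calcium_mM", "sweep_index", "time_ms", "voltage_mV", "current_pA"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
            raise SweepFormatError(
                f"{csv_path}: non-numeric value in column {col!r} at line {line}"
            )
        df[col] = numeric

    n_expected = len(protocol.time_base_ms())
    out: Dict[str, List[PatchPair]] = {}
    for construct, entries in sidecar["constructs"].items():
        plist: List[PatchPair] = []
        for entry in entries:
            pid = entry["patch_id"]
            ion = IonSpec(**entry["ion"])
            tp = entry.get("true_params")
            params = BarrierModelParams(**tp) if tp else None
            recs = {}
            for calcium, grp in df[df.patch_id == pid].groupby("calcium_mM"):
                sweeps = []
                for s_idx, sg in grp.groupby("sweep_index"):
                    if len(sg) != n_expected:
                        line = int(sg.index[0]) + 2
                        raise SweepFormatError(
                            f"{csv_path}: sweep {int(s_idx)} of patch {pid!r} has "
                            f"{len(sg)} samples, expected {n_expected} (near line {line})"
                        )
                    sweeps.append(
                        Sweep(
                            int(s_idx),
                            float(sg["voltage_mV"].iloc[-1]),
                            sg["voltage_mV"].to_numpy(),
                            sg["current_pA"].to_numpy(),
                        )
                    )
                sweeps.sort(key=lambda s: s.sweep_index)
                recs[calcium] = PatchRecording(
                    patch_id=pid,
                    protocol=protocol,
                    sweeps=sweeps,
                    ion=ion,
                    calcium_mM=float(calcium),
                    voltage_offset_mV=entry.get("voltage_offset_mV", 0.0),
                    true_params=params if calcium > 0 else None,
                    thermo=thermo,
                )
            test = next((r for c, r in recs.items() if c > 0), None)
            background = recs.get(0.0)
            if test is None or background is None:
                raise SweepFormatError(
                    f"{csv_path}: patch {pid!r} lacks a test/background pair"
                )
            plist.append(PatchPair(test=test, background=background))
        out[construct] = plist
    return out


def write_iv_table(curves: Mapping[str, IVCurve], path: Path) -> None:
    """Tidy aggregated I-V table: construct, voltage_mV, mean, sem, n."""
    rows = []
    for construct, curve in curves.items():
        sem = curve.sem if curve.sem is not None else np.zeros_like(curve.currents)
        for v, i, s in zip(curve.voltages, curve.currents, sem):
            rows.append(
                {
                    "construct": construct,
                    "voltage_mV": v,
                    "mean_norm_current": i,
                    "sem": s,
                    "n_patches": curve.n_patches,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_iv_table(path: Path) -> Dict[str, IVCurve]:
    df = pd.read_csv(path)
    out: Dict[str, IVCurve] = {}
    for construct, grp in df.groupby("construct", sort=False):
        grp = grp.sort_values("voltage_mV")
        n = grp["n_patches"].iloc[0]
        out[str(construct)] = IVCurve(
            grp["voltage_mV"].to_numpy(),
            grp["mean_norm_current"].to_numpy(),
            sem=grp["sem"].to_numpy(),
            normalization=Normalization.NORMALIZED_TO_PLUS120MV,
            n_patches=None if pd.isna(n) else int(n),
        )
    return out


def fit_result_to_dict(fit: FitResult) -> Dict:
    return {
        "n_barriers": fit.n_barriers_fixed,
        "sigma_beta": fit.params_hat.sigma_beta,
        "sigma_h": fit.params_hat.sigma_h,
        "amplitude": fit.params_hat.amplitude,
        "delta_ea_in_minus_out_kJ_per_mol": fit.energy_profile.delta_ea_in_minus_out,
        "delta_ea_mid_minus_out_kJ_per_mol": fit.energy_profile.delta_ea_mid_minus_out,
        "rectification_index": fit.rectification_index,
        "residual_norm": fit.residual_norm,
        "ci_sigma_beta": list(fit.ci_sigma_beta),
        "ci_sigma_h": list(fit.ci_sigma_h),
        "converged": fit.converged,
    }


def write_fit_results(fits: Mapping[str, FitResult], path: Path) -> None:
    payload = {name: fit_result_to_dict(f) for name, f in fits.items()}
    Path(path).write_text(json.dumps(payload, indent=1))
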
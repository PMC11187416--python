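"""File I/O: spectrum CSV dialect, JCAMP-DX ingest, RunLog and template files.

Native spectrum CSV is two columns ``wavenumber_cm-1,absorbance`` with a
mandatory header, one spectrum per file; multi-spectrum time series use a long
table with a leading ``time_h`` column. Spectra are stored ascending in
wavenumber regardless of file order; re-sorted input is flagged in the
spectrum's ``meta``. RunLog and metric CSVs carry the config hash and seed in
leading ``#`` comment lines so every artifact is traceable to its frozen
configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationTemplate, FitStats, PairedObservation
from .errors import SpectrumParseError
from .spectra import BandDefinition, Spectrum

SPECTRUM_HEADER = ["wavenumber_cm-1", "absorbance"]


def write_spectrum_csv(s: Spectrum, path) -> None:
    """Write one spectrum at full float precision (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write(",".join(SPECTRUM_HEADER) + "\n")
        for w, a in zip(s.wavenumbers, s.absorbance):
            fh.write(f"{float(w)!r},{float(a)!r}\n")


def read_spectrum_csv(path) -> Spectrum:
    """Read a native spectrum CSV; errors carry the offending line number."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split(",") != SPECTRUM_HEADER:
            raise SpectrumParseError(
                f"{path}:1: expected header {','.join(SPECTRUM_HEADER)!r}, "
                f"got {header!r}"
            )
        wavenumbers, absorbance = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected 2 fields")
            try:
                wavenumbers.append(float(parts[0]))
                absorbance.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: {exc}") from None
    w = np.array(wavenumbers)
    a = np.array(absorbance)
    meta = {"source": str(path), "resorted": False}
    if np.any(np.diff(w) < 0):
        order = np.argsort(w, kind="stable")
        w, a = w[order], a[order]
        meta["resorted"] = True
        meta["original_order"] = "descending-or-mixed"
    return Spectrum(w, a, label=path.stem, meta=meta)


def write_spectra_timeseries(spectra: list[tuple[float, Spectrum]], path) -> None:
    """Write (time_h, spectrum) pairs as one long CSV."""
    frames = []
    for t, s in spectra:
        frames.append(pd.DataFrame({
            "time_h": t,
            "wavenumber_cm-1": s.wavenumbers,
            "absorbance": s.absorbance,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_timeseries(path) -> list[tuple[float, Spectrum]]:
    df = pd.read_csv(path)
    expected = ["time_h", *SPECTRUM_HEADER]
    if list(df.columns) != expected:
        raise SpectrumParseError(f"{path}: expected columns {expected}")
    out = []
    for t, grp in df.groupby("time_h", sort=True):
        out.append((float(t), Spectrum(
            grp["wavenumber_cm-1"].to_numpy(), grp["absorbance"].to_numpy(),
            label=f"t={t}h")))
    return out


def read_jcamp(path) -> Spectrum:
    """Minimal JCAMP-DX reader: AFFN ``##XYDATA=(X++(Y..Y))`` blocks only.

    Applies XFACTOR/YFACTOR; compressed ordinate forms (SQZ/DIF/DUP) are not
    supported. Good enough to ingest spectra exported by instrument software
    in the plain numeric dialect.
    """
    path = Path(path)
    xfactor = yfactor = 1.0
    deltax = None
    in_data = False
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                if key == "XFACTOR":
                    xfactor = float(val)
                elif key == "YFACTOR":
                    yfactor = float(val)
                elif key == "DELTAX":
                    deltax = float(val)
                elif key == "XYDATA":
                    if "X++" not in val.replace(" ", ""):
                        raise SpectrumParseError(
                            f"{path}:{lineno}: unsupported XYDATA form {val!r}")
                    in_data = True
                elif key == "END":
                    in_data = False
                continue
            if in_data:
                try:
                    nums = [float(tok) for tok in line.replace(",", " ").split()]
                except ValueError as exc:
                    raise SpectrumParseError(f"{path}:{lineno}: {exc}") from None
                if len(nums) < 2:
                    raise SpectrumParseError(
                        f"{path}:{lineno}: XYDATA line needs X plus >=1 Y")
                x0 = nums[0] * xfactor
                yvals = [n * yfactor for n in nums[1:]]
                if deltax is None and len(yvals) > 1:
                    raise SpectrumParseError(
                        f"{path}:{lineno}: multiple Y per line requires ##DELTAX")
                step = deltax if deltax is not None else 0.0
                for k, y in enumerate(yvals):
                    xs.append(x0 + k * step)
                    ys.append(y)
    if not xs:
        raise SpectrumParseError(f"{path}: no XYDATA block found")
    w = np.array(xs)
    a = np.array(ys)
    meta = {"source": str(path), "format": "jcamp-dx", "resorted": False}
    if np.any(np.diff(w) < 0):
        order = np.argsort(w, kind="stable")
        w, a = w[order], a[order]
        meta["resorted"] = True
    return Spectrum(w, a, label=path.stem, meta=meta)


def _provenance_header(config_hash: str | None, seed: int | None) -> str:
    parts = []
    if config_hash is not None:
        parts.append(f"# config_sha256={config_hash}")
    if seed is not None:
        parts.append(f"# seed={seed}")
    return "".join(p + "\n" for p in parts)


def write_runlog_csv(runlog: pd.DataFrame, path, config_hash=None, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config_hash, seed))
        runlog.to_csv(fh, index=False)


def read_runlog_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_table_csv(df: pd.DataFrame, path, config_hash=None, seed=None) -> None:
    """Write any tidy metrics table with the provenance comment header."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(config_hash, seed))
        df.to_csv(fh, index=False)


def write_summary_jsonl(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, default=float) + "\n")


def write_template(template: CalibrationTemplate, path) -> None:
    """Persist a calibration template as flat structured text (YAML)."""
    doc = {
        "analyte": template.analyte,
        "slope": template.slope,
        "intercept": template.intercept,
        "band": {
            "location_window": list(template.band.location_window),
            "baseline_window": list(template.band.baseline_window),
            "nominal_center": template.band.nominal_center,
        },
    }
    if template.fit_stats is not None:
        doc["fit_stats"] = {
            "n": template.fit_stats.n,
            "r_squared": template.fit_stats.r_squared,
            "residual_sd": template.fit_stats.residual_sd,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_template(path) -> CalibrationTemplate:
    doc = yaml.safe_load(Path(path).read_text())
    band = BandDefinition(
        analyte=doc["analyte"],
        location_window=tuple(doc["band"]["location_window"]),
        baseline_window=tuple(doc["band"]["baseline_window"]),
        nominal_center=doc["band"]["nominal_center"],
    )
    fs = doc.get("fit_stats")
    return CalibrationTemplate(
        analyte=doc["analyte"], band=band, slope=doc["slope"],
        intercept=doc["intercept"],
        fit_stats=FitStats(**fs) if fs else None,
    )


def read_paired_observations(path) -> list[PairedObservation]:
    """Read the calibration CSV: absorbance,concentration_g_per_L[,time_h,run_id]."""
    df = pd.read_csv(path, comment="#")
    required = ["absorbance", "concentration_g_per_L"]
    for col in required:
        if col not in df.columns:
            raise SpectrumParseError(f"{path}: missing column {col!r}")
    return [
        PairedObservation(
            absorbance=float(row["absorbance"]),
            reference_concentration=float(row["concentration_g_per_L"]),
            time=float(row.get("time_h", 0.0) or 0.0) if "time_h" in df else 0.0,
            run_id=str(row["run_id"]) if "run_id" in df else "",
        )
        for _, row in df.iterrows()
    ]
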
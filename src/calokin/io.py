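"""Reading and writing the package's plain-text file dialects.

Three CSV dialects, all comment-headed and loss-free:

* thermogram — ``# calokin-thermogram v1`` marker, ``# key=value``
  metadata lines (cell_volume_ul, enzyme_uM, s0_uM, cosubstrate_uM,
  p0_uM, temp_C, injection_end_s), then ``time_s,power_ucal_per_s``;
* rate profile — ``s_uM,v_uM_per_s``;
* titration — ``# calokin-titration v1`` marker, metadata
  (cell_volume_ul, cell_conc_uM, syringe_conc_uM, temp_C), then
  ``injection_ul,heat_ucal``.

Writers emit exactly these dialects (comma-separated, ``%.10g``
numbers); readers accept comma or tab separation. Ground truth travels
as a JSON sidecar (``*.truth.json``).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .itc import Titration
from .synthetic import GroundTruth
from .thermogram import RateProfile, Thermogram, ThermogramMeta
from .units import celsius_to_kelvin, kelvin_to_celsius

__all__ = [
    "write_thermogram", "read_thermogram",
    "write_rate_profile", "read_rate_profile",
    "write_titration", "read_titration",
    "write_truth",
]

_FMT = "%.10g"


def _fmt(x: float) -> str:
    return _FMT % x


def _read_commented_csv(path, marker: str, required_keys: tuple[str, ...],
                        columns: tuple[str, ...]):
    """Parse a comment-headed CSV; returns (meta dict, DataFrame)."""
    path = Path(path)
    meta: dict[str, float] = {}
    data_lines: list[str] = []
    header_seen = False
    try:
        text = path.read_text()
    except OSError as e:
        raise ParseError(f"cannot read file: {e}", path=path) from e
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if lineno == 1:
                if body != marker:
                    raise ParseError(f"expected dialect marker '{marker}', "
                                     f"got '{body}'", path=path, line=1)
                header_seen = True
                continue
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                try:
                    meta[key] = float(val.strip())
                except ValueError as e:
                    raise ParseError("metadata value is not numeric",
                                     path=path, line=lineno, field=key) from e
            continue
        data_lines.append(raw)
    if not header_seen:
        raise ParseError(f"missing dialect marker '{marker}' on line 1", path=path)
    for key in required_keys:
        if key not in meta:
            raise ParseError("missing metadata key", path=path, field=key)
    try:
        df = pd.read_csv(_io.StringIO("\n".join(data_lines)), sep=r"[,\t]",
                         engine="python")
    except Exception as e:
        raise ParseError(f"cannot parse data table: {e}", path=path) from e
    got = tuple(c.strip() for c in df.columns)
    if got != columns:
        raise ParseError(f"expected columns {columns}, got {got}", path=path,
                         field=",".join(got))
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise ParseError("non-numeric or missing value in data row",
                         path=path, line=bad + 2 + len(meta),
                         field=str(df.columns[df.iloc[bad].isna().argmax()]))
    return meta, df


# ---------------------------------------------------------------------------
# thermograms

_THERMO_MARKER = "calokin-thermogram v1"
_THERMO_KEYS = ("cell_volume_ul", "enzyme_uM", "s0_uM", "cosubstrate_uM",
                "p0_uM", "temp_C", "injection_end_s")


def write_thermogram(g: Thermogram, path) -> None:
    m = g.meta
    lines = [f"# {_THERMO_MARKER}",
             f"# cell_volume_ul={_fmt(m.cell_volume * 1e6)}",
             f"# enzyme_uM={_fmt(m.enzyme * 1e6)}",
             f"# s0_uM={_fmt(m.s0 * 1e6)}",
             f"# cosubstrate_uM={_fmt(m.cosubstrate * 1e6)}",
             f"# p0_uM={_fmt(m.p0 * 1e6)}",
             f"# temp_C={_fmt(kelvin_to_celsius(m.temperature))}",
             f"# injection_end_s={_fmt(m.injection_end)}",
             "time_s,power_ucal_per_s"]
    lines += [f"{_fmt(t)},{_fmt(p)}" for t, p in zip(g.t, g.power)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_thermogram(path) -> Thermogram:
    meta, df = _read_commented_csv(path, _THERMO_MARKER, _THERMO_KEYS,
                                   ("time_s", "power_ucal_per_s"))
    tm = ThermogramMeta(
        cell_volume=meta["cell_volume_ul"] * 1e-6,
        enzyme=meta["enzyme_uM"] * 1e-6,
        s0=meta["s0_uM"] * 1e-6,
        cosubstrate=meta["cosubstrate_uM"] * 1e-6,
        p0=meta["p0_uM"] * 1e-6,
        temperature=celsius_to_kelvin(meta["temp_C"]),
        injection_end=meta["injection_end_s"],
    )
    return Thermogram(t=df["time_s"].to_numpy(float),
                      power=df["power_ucal_per_s"].to_numpy(float),
                      meta=tm, source_id=Path(path).stem)


# ---------------------------------------------------------------------------
# rate profiles


def write_rate_profile(p: RateProfile, path) -> None:
    lines = ["s_uM,v_uM_per_s"]
    lines += [f"{_fmt(s * 1e6)},{_fmt(v * 1e6)}" for s, v in zip(p.s, p.v)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_rate_profile(path) -> RateProfile:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"[,\t]", engine="python", comment="#")
    except Exception as e:
        raise ParseError(f"cannot parse rate profile: {e}", path=path) from e
    cols = tuple(c.strip() for c in df.columns)
    if cols != ("s_uM", "v_uM_per_s"):
        raise ParseError(f"expected columns ('s_uM', 'v_uM_per_s'), got {cols}",
                         path=path)
    return RateProfile(s=df["s_uM"].to_numpy(float) * 1e-6,
                       v=df["v_uM_per_s"].to_numpy(float) * 1e-6,
                       source_id=path.stem)


# ---------------------------------------------------------------------------
# titrations

_TITR_MARKER = "calokin-titration v1"
_TITR_KEYS = ("cell_volume_ul", "cell_conc_uM", "syringe_conc_uM", "temp_C")


def write_titration(t: Titration, path) -> None:
    if t.heats is None:
        heats = np.zeros(t.n_injections)
    else:
        heats = t.heats
    lines = [f"# {_TITR_MARKER}",
             f"# cell_volume_ul={_fmt(t.cell_volume * 1e6)}",
             f"# cell_conc_uM={_fmt(t.cell_conc * 1e6)}",
             f"# syringe_conc_uM={_fmt(t.syringe_conc * 1e6)}",
             f"# temp_C={_fmt(kelvin_to_celsius(t.temperature))}",
             "injection_ul,heat_ucal"]
    lines += [f"{_fmt(v * 1e6)},{_fmt(h)}"
              for v, h in zip(t.injection_volumes, heats)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_titration(path) -> Titration:
    meta, df = _read_commented_csv(path, _TITR_MARKER, _TITR_KEYS,
                                   ("injection_ul", "heat_ucal"))
    return Titration(
        cell_volume=meta["cell_volume_ul"] * 1e-6,
        cell_conc=meta["cell_conc_uM"] * 1e-6,
        syringe_conc=meta["syringe_conc_uM"] * 1e-6,
        injection_volumes=df["injection_ul"].to_numpy(float) * 1e-6,
        heats=df["heat_ucal"].to_numpy(float),
        temperature=celsius_to_kelvin(meta["temp_C"]),
        label=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# ground truth sidecars


def write_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True)
                          + "\n")
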
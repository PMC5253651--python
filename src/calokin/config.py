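"""Run configuration: documented defaults, config-file parsing, overrides.

Configuration is a flat text file of dotted keys, one ``key = value``
per line, ``#`` comments allowed::

    fit_kinetics.kp_uM = 6
    rpka.threshold = 0.05

Unknown keys are rejected. Resolution order (lowest to highest):
built-in defaults → config file → command-line flags. Every resolved
configuration is embedded in the command's JSON report for provenance.
"""

from __future__ import annotations

from pathlib import Path

from .errors import InvalidInputError

__all__ = ["DEFAULTS", "load_config_file", "resolve"]

# key: (default, type, help)
DEFAULTS: dict[str, tuple] = {
    # simulation — study conditions of the emulated experiments
    "simulate.seed": (0, int, "base RNG seed"),
    "simulate.tau_s": (10.0, float, "instrument response time constant (s)"),
    "simulate.dt_s": (1.0, float, "sampling interval (s)"),
    "simulate.noise_power_sd_ucal": (0.02, float, "power noise s.d. (ucal/s)"),
    "simulate.noise_heat_frac": (0.02, float, "heat noise fraction"),
    "simulate.excess_uM": (24.0, float, "same-excess [A]0-[B]0 (uM)"),
    "simulate.b0_levels_uM": ("16,40", str, "limiting-substrate levels (uM, comma-separated)"),
    "simulate.enzyme_nM": (450.0, float, "assay enzyme concentration (nM)"),
    "simulate.kcat_per_s": (0.90, float, "turnover number (1/s)"),
    "simulate.km_uM": (1.1, float, "Michaelis constant (uM)"),
    "simulate.kp_uM": (6.0, float, "product affinity term (uM); 0 disables"),
    "simulate.dh_kcal_mol": (-22.5, float, "reaction enthalpy (kcal/mol)"),
    "simulate.transient_s": (20.0, float, "mixing transient width (s)"),
    "simulate.titr_n": (1.12, float, "titration true stoichiometry"),
    "simulate.titr_kd_uM": (5.3, float, "titration true Kd (uM)"),
    "simulate.titr_dh_kcal_mol": (-5.5, float, "titration true dH (kcal/mol)"),
    "simulate.titr_cell_uM": (100.0, float, "titration cell concentration (uM)"),
    "simulate.titr_syringe_uM": (1500.0, float, "titration syringe ligand (uM)"),
    "simulate.temp_C": (30.0, float, "temperature (C)"),
    # thermogram processing
    "process.tau_s": (10.0, float, "time-constant correction tau (s)"),
    "process.induction": ("default", str, "induction cutoff: 'default', 'auto' or seconds"),
    "process.bin_k": (1, int, "bin size for display profiles"),
    # kinetics fitting
    "fit_kinetics.kp_uM": (6.0, float, "fixed product affinity term (uM); 0 = none"),
    # binding fitting
    "fit_binding.c_min": (5.0, float, "low-c threshold for fixing n at 1"),
    "fit_binding.skip_first": (1, int, "exclude the first (small) injection"),
    # rpka
    "rpka.threshold": (0.05, float, "overlay rms threshold"),
    "rpka.smooth_window": (23, int, "Savitzky-Golay window for overlay rates"),
    "rpka.rate_floor_frac": (0.5, float, "exclude reference rates below this fraction of max"),
    "rpka.induction_extra_s": (5.0, float, "overlay trim margin past injection end (s)"),
    # thermo
    "thermo.temp_C": (30.0, float, "temperature (C) for dG/TdS"),
}


def load_config_file(path) -> dict:
    """Parse a flat key=value config file, rejecting unknown keys."""
    out: dict = {}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidInputError(
                f"{path}:{lineno}: expected 'key = value', got '{raw.strip()}'")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in DEFAULTS:
            raise InvalidInputError(f"{path}:{lineno}: unknown config key '{key}'")
        typ = DEFAULTS[key][1]
        try:
            out[key] = typ(val.strip())
        except ValueError as e:
            raise InvalidInputError(
                f"{path}:{lineno}: cannot parse '{val.strip()}' as "
                f"{typ.__name__} for '{key}'") from e
    return out


def resolve(prefix: str, file_cfg: dict | None = None, **overrides) -> dict:
    """Resolved configuration for one command section.

    Returns short-key → value for all ``prefix.*`` defaults, updated by
    the config file and then by non-None keyword overrides.
    """
    cfg = {k.split(".", 1)[1]: v for k, (v, _, _) in DEFAULTS.items()
           if k.startswith(prefix + ".")}
    if file_cfg:
        for k, v in file_cfg.items():
            if k.startswith(prefix + "."):
                cfg[k.split(".", 1)[1]] = v
    for k, v in overrides.items():
        if v is not None:
            if k not in cfg:
                raise InvalidInputError(f"unknown option '{prefix}.{k}'")
            cfg[k] = v
    return cfg


def show_config() -> str:
    lines = []
    for key, (default, typ, help_) in DEFAULTS.items():
        lines.append(f"{key} = {default}  # {help_} [{typ.__name__}]")
    return "\n".join(lines)
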
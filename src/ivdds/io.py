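"""Structured config handling, CSV time-series dialects and run provenance.

CSV is the single time-series interchange format; column names carry
their unit as a suffix (``time_s``, ``temperature_C``, ``I_v_au``,
``conc_ug_ml``) and the time column must be strictly increasing.
Parameter bundles travel as a JSON tree with fixed sections
``tumor_transport``, ``systemic_pk``, ``geometry`` and (optionally)
``dose``.  Floats are serialized with 17 significant digits so that a
write/read round trip is exact.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import platform
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, InputError
from .params import (
    DoseSpec,
    ParameterBundle,
    SystemicPK,
    TumorGeometry,
    TumorTransport,
    validate_params,
)

_SCHEMA = {
    "tumor_transport": {"v_p", "v_e_av", "TT", "PS", "Hct_mv", "F_p",
                        "v_v", "v_e", "k_av", "sd"},
    "systemic_pk": {"V_D", "V_p_S", "k_p", "k_t", "k_e", "sd"},
    "geometry": {"VT", "V_p_T", "sd"},
    "dose": {"ID", "form"},
    "notes": None,
}
_REQUIRED = {
    "tumor_transport": {"v_p", "v_e_av", "TT", "PS"},
    "systemic_pk": {"V_D", "V_p_S", "k_p", "k_t", "k_e"},
    "geometry": {"VT"},
}

#: Packaged parameter fixture with the in-vivo measured tumor transport
#: and pharmacokinetic values for the carboxyfluorescein dye system.
TABLE1_PATH = Path(__file__).parent / "data" / "table1.json"


def load_config(path) -> tuple[ParameterBundle, Optional[DoseSpec]]:
    """Load and validate a parameter config file.

    Unknown keys are rejected with the path to the offending key; all
    parameter invariants are checked and derived fields filled in.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be an object")

    for section, keys in raw.items():
        if section not in _SCHEMA:
            raise ConfigurationError(f"{path}: unknown section {section!r}")
        if _SCHEMA[section] is None:
            continue
        if not isinstance(keys, dict):
            raise ConfigurationError(f"{path}: section {section!r} must be an object")
        for key in keys:
            if key not in _SCHEMA[section]:
                raise ConfigurationError(
                    f"{path}: unknown key {section}.{key}")
    for section, required in _REQUIRED.items():
        if section not in raw:
            raise ConfigurationError(f"{path}: missing section {section!r}")
        missing = required - set(raw[section])
        if missing:
            raise ConfigurationError(
                f"{path}: section {section!r} missing keys {sorted(missing)}")

    tumor = TumorTransport(**raw["tumor_transport"])
    pk = SystemicPK(**raw["systemic_pk"])
    geometry = TumorGeometry(**raw["geometry"])
    bundle = validate_params(tumor, pk, geometry)
    dose = DoseSpec(**raw["dose"]) if "dose" in raw else None
    return bundle, dose


def load_reference_params() -> ParameterBundle:
    """The packaged in-vivo parameter set (see data/table1.json)."""
    bundle, _ = load_config(TABLE1_PATH)
    return bundle


def save_config(bundle: ParameterBundle, path,
                dose: Optional[DoseSpec] = None) -> None:
    tree = {
        "tumor_transport": _section(bundle.tumor,
                                    ("v_p", "v_e_av", "TT", "PS", "Hct_mv",
                                     "F_p", "v_v", "v_e", "k_av")),
        "systemic_pk": _section(bundle.pk, ("V_D", "V_p_S", "k_p", "k_t", "k_e")),
        "geometry": _section(bundle.geometry, ("VT", "V_p_T")),
    }
    if dose is not None:
        tree["dose"] = {"ID": dose.ID, "form": dose.form}
    Path(path).write_text(json.dumps(tree, indent=2) + "\n")


def _section(obj, fields):
    out = {}
    for f in fields:
        v = getattr(obj, f)
        if v is not None:
            out[f] = v
    if obj.sd:
        out["sd"] = dict(obj.sd)
    return out


_UNIT_SUFFIXES = ("_s", "_min", "_C", "_au", "_ug_ml", "_frac", "_pct")


def read_timeseries_csv(path, expected_columns: Sequence[str]) -> pd.DataFrame:
    """Read a time-series CSV, enforcing columns and monotone time.

    The first expected column is the time axis; a ``_min`` suffix is
    converted to seconds (column renamed accordingly).  Column names
    must carry a recognized unit suffix.
    """
    path = Path(path)
    for col in expected_columns:
        if not col.endswith(_UNIT_SUFFIXES):
            raise InputError(
                f"{path}: expected column {col!r} lacks a unit suffix "
                f"(one of {_UNIT_SUFFIXES})")
    df = pd.read_csv(path)
    missing = [c for c in expected_columns
               if c not in df.columns and not _minute_variant(c, df)]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}; "
                         f"found {list(df.columns)}")
    tcol = expected_columns[0]
    if tcol not in df.columns and tcol.endswith("_s"):
        alt = tcol[:-2] + "_min"
        df[tcol] = df[alt] * 60.0
        df = df.drop(columns=[alt])
    t = df[tcol].to_numpy()
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise InputError(
            f"{path}: time column {tcol!r} not strictly increasing at "
            f"data line {bad[0] + 3}")   # +1 header, +1 one-based, +1 later row
    return df[list(expected_columns)]


def _minute_variant(col: str, df) -> bool:
    return col.endswith("_s") and (col[:-2] + "_min") in df.columns


def write_timeseries_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    config: dict
    seed: Optional[int] = None
    version: str = __version__
    input_digests: dict = dataclasses.field(default_factory=dict)
    timestamp: str = ""
    platform: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()
        if not self.platform:
            self.platform = platform.platform()

    @staticmethod
    def digest(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def add_input(self, path) -> None:
        self.input_digests[str(path)] = self.digest(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str) + "\n")
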
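"""CSV interchange for trials and imputed datasets.

Wide patient-level CSV with columns ``patient_id, arm, y0..yJ,
disc_time, withdrawn``; missing outcomes serialise as empty fields.
Stacked imputation files carry an additional leading ``imputation``
column (1..m).  Every file written by the package starts with a comment
header recording the version and the seed used, which the readers skip.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .simulate import TrialData

__all__ = [
    "write_trial_csv",
    "read_trial_csv",
    "write_stacked_csv",
    "read_stacked_csv",
    "write_result_csv",
]


def _header(seed) -> str:
    return f"# offtreat {__version__} seed={seed}\n"


def _write(df: pd.DataFrame, path, seed) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, index=False, lineterminator="\n")


def write_trial_csv(trial: TrialData, path, seed="unset") -> None:
    df = trial.df.copy()
    df["withdrawn"] = df["withdrawn"].astype(int)
    _write(df, path, seed)


def _frame_to_trial(df: pd.DataFrame) -> TrialData:
    ycols = sorted(
        (c for c in df.columns if c.startswith("y") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not ycols or ycols[0] != "y0":
        raise ValueError("trial CSV must contain columns y0..yJ")
    J = int(ycols[-1][1:])
    required = {"patient_id", "arm", "disc_time", "withdrawn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV is missing column(s): {sorted(missing)}")
    out = df.copy()
    out["withdrawn"] = out["withdrawn"].astype(int).astype(bool)
    out["disc_time"] = out["disc_time"].astype(int)
    out[ycols] = out[ycols].astype(float)
    return TrialData(df=out, J=J)


def read_trial_csv(path) -> TrialData:
    df = pd.read_csv(path, comment="#")
    return _frame_to_trial(df)


def write_stacked_csv(stacked: pd.DataFrame, path, seed="unset") -> None:
    df = stacked.copy()
    df["withdrawn"] = df["withdrawn"].astype(int)
    _write(df, path, seed)


def read_stacked_csv(path) -> list:
    """Read a stacked imputation CSV into a list of completed trials."""
    df = pd.read_csv(path, comment="#")
    if "imputation" not in df.columns:
        raise ValueError("stacked CSV must contain an 'imputation' column")
    out = []
    for _, group in df.groupby("imputation", sort=True):
        out.append(_frame_to_trial(group.drop(columns="imputation").reset_index(drop=True)))
    return out


def write_result_csv(row: dict, path, seed="unset") -> None:
    _write(pd.DataFrame([row]), path, seed)
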
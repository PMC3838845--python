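"""CSV input/output and programmatic fixture generation.

Data files are plain CSV with a header: a binary ``status`` column (0 =
non-diseased, 1 = diseased), a continuous response ``y``, and one column per
covariate.  Column order in the file is irrelevant; covariate order follows
the header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import TwoGroupSample
from .simulate import generate_setting_data, make_setting

__all__ = ["read_two_group_csv", "write_two_group_csv", "write_fixture", "covariate_names"]


def covariate_names(path: str | Path) -> list[str]:
    header = pd.read_csv(path, nrows=0)
    return [c for c in header.columns if c not in ("status", "y")]


def read_two_group_csv(path: str | Path) -> TwoGroupSample:
    """Load a two-group sample, partitioning rows by the ``status`` column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("status", "y"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    cov_cols = [c for c in df.columns if c not in ("status", "y")]
    if not cov_cols:
        raise ValueError("no covariate columns found")
    if df[cov_cols + ["y"]].isna().any().any():
        raise ValueError("NA cells are not allowed")
    bad = df.index[~df["status"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"non-binary status value at row {int(bad[0])}")
    nd = df[df["status"] == 0]
    dd = df[df["status"] == 1]
    if len(nd) < 2 or len(dd) < 2:
        raise ValueError("need at least 2 rows per disease group")
    return TwoGroupSample(
        y_nondiseased=nd["y"].to_numpy(float),
        y_diseased=dd["y"].to_numpy(float),
        z_nondiseased=nd[cov_cols].to_numpy(float),
        z_diseased=dd[cov_cols].to_numpy(float),
    )


def write_two_group_csv(sample: TwoGroupSample, path: str | Path, names=None) -> Path:
    path = Path(path)
    d = sample.d
    names = list(names) if names is not None else [f"z{j+1}" for j in range(d)]
    status = np.concatenate([np.zeros(sample.n_nondiseased, int), np.ones(sample.n_diseased, int)])
    y = np.concatenate([sample.y_nondiseased, sample.y_diseased])
    Z = np.vstack([sample.z_nondiseased, sample.z_diseased])
    df = pd.DataFrame({"status": status, "y": y})
    for j, name in enumerate(names):
        df[name] = Z[:, j]
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def write_fixture(setting_id: int, seed: int, path: str | Path) -> Path:
    """Write one simulated draw of a benchmark setting as a CSV fixture."""
    setting = make_setting(setting_id)
    sample = generate_setting_data(setting, seed)
    return write_two_group_csv(sample, path)
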
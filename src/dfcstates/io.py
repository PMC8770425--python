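"""Plain-text input/output for cohort data.

ROI time series travel as tab-separated text: one file per subject-session,
T rows, an index column ``t`` plus one column per ROI (atlas order).  The
clinical table is a CSV with the documented header.  File names follow
``<subject_id>_<session>.tsv``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .windows import SubjectTimeSeries

CLINICAL_COLUMNS = [
    "subject_id", "group", "age", "sex", "mean_fd",
    "hamd_baseline", "hamd_week12", "rr", "responder",
]


def write_timeseries(ts: SubjectTimeSeries, directory: str | Path, roi_names=None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = roi_names or [f"roi{i + 1}" for i in range(ts.n_rois)]
    df = pd.DataFrame(ts.data, columns=cols)
    df.insert(0, "t", np.arange(ts.n_timepoints))
    path = directory / f"{ts.subject_id}_{ts.session}.tsv"
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_timeseries(path: str | Path, subject_id=None, group="HC", session=None) -> SubjectTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "t" in df.columns:
        df = df.drop(columns="t")
    stem = path.stem
    if subject_id is None or session is None:
        sid, _, sess = stem.rpartition("_")
        subject_id = subject_id or sid or stem
        session = session or (sess if sess in ("baseline", "post") else "baseline")
    return SubjectTimeSeries(
        subject_id=subject_id, group=group, session=session, data=df.to_numpy(float)
    )


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df


def read_cohort(directory: str | Path, clinical_path: str | Path | None = None):
    """Load every ``*_baseline.tsv`` / ``*_post.tsv`` plus the clinical CSV."""
    directory = Path(directory)
    clinical_path = clinical_path or directory / "clinical.csv"
    clinical = read_clinical(clinical_path)
    groups = clinical.set_index("subject_id")["group"].to_dict()
    series = []
    for f in sorted(directory.glob("*_baseline.tsv")) + sorted(directory.glob("*_post.tsv")):
        sid, _, sess = f.stem.rpartition("_")
        series.append(read_timeseries(f, subject_id=sid, group=groups.get(sid, "HC"), session=sess))
    if not series:
        raise ValueError(f"no time-series files found in {directory}")
    return series, clinical
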
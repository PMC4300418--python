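"""NONMEM-dialect longitudinal trial datasets.

One rectangular CSV per trial with columns

    ID, TIME (days), DV (L), AMT (ug), II (days), ADDL, EVID, MDV,
    DROPOUT, ARM, AGE, SEX, HT, WT, BMI, SEV, REV, PICS, SMOK

Row kinds: observation (EVID=0, MDV=0, DV present), dose (EVID=1, AMT/II/
ADDL encode the repeated BID regimen), dropout terminal record (EVID=3,
DROPOUT=1, TIME = the first scheduled visit after the subject left).
Categorical covariates are 0/1 flags for the non-reference level
(SEX: 1=male, SEV: 1=severe, REV/PICS/SMOK: 1=yes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import DoseRegimen

__all__ = ["LongitudinalDataset", "read_dataset", "write_dataset"]

_COV_MAP = {
    "age": "AGE",
    "sex": "SEX",
    "height": "HT",
    "weight": "WT",
    "bmi": "BMI",
    "severity": "SEV",
    "reversibility": "REV",
    "pics": "PICS",
    "smoking": "SMOK",
}
_COLUMNS = (
    ["ID", "TIME", "DV", "AMT", "II", "ADDL", "EVID", "MDV", "DROPOUT", "ARM"]
    + list(_COV_MAP.values())
)


@dataclass
class _Packed:
    """Grid-aligned arrays consumed by the vectorised likelihood engine."""

    ids: np.ndarray  # (n,)
    times: np.ndarray  # (m,) days, times[0] == 0
    y: np.ndarray  # (n, m) DV, NaN where unobserved
    dose_amount: np.ndarray  # (n,) ug
    dose_interval: float  # hours
    dropped: np.ndarray  # (n,) bool
    event_idx: np.ndarray  # (n,) grid index of the first missed visit; -1 if completed
    covariates: pd.DataFrame  # numeric, lower-case names
    arm: np.ndarray  # (n,) labels

    @property
    def horizon_days(self) -> float:
        return float(self.times[-1])


class LongitudinalDataset:
    """Observation/dose/dropout records for many subjects."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        ids: np.ndarray,
        times: np.ndarray,
        y: np.ndarray,
        regimens: list[DoseRegimen],
        arm: np.ndarray,
        covariates: pd.DataFrame,
        dropped: np.ndarray,
        event_idx: np.ndarray,
    ) -> "LongitudinalDataset":
        """Assemble the rectangular table from simulator arrays (see
        :class:`_Packed` for shapes; ``regimens`` has one entry per subject)."""
        rows = []
        m = len(times)
        for i, sid in enumerate(ids):
            cov = {
                _COV_MAP[k]: float(covariates.iloc[i][k]) for k in _COV_MAP
            }
            base = dict(ARM=arm[i], DROPOUT=0, **cov)
            last = event_idx[i] - 1 if dropped[i] else m - 1
            for j in range(last + 1):
                rows.append(
                    dict(
                        ID=sid, TIME=times[j], DV=y[i, j], AMT=np.nan, II=np.nan,
                        ADDL=np.nan, EVID=0, MDV=0, **base,
                    )
                )
            reg = regimens[i]
            if not reg.is_placebo:
                n_doses = int(
                    np.floor((min(reg.end_time, times[-1]) - reg.start_time)
                             / reg.interval_days + 1e-9)
                ) + 1
                rows.append(
                    dict(
                        ID=sid, TIME=reg.start_time, DV=np.nan,
                        AMT=reg.dose_amount, II=reg.interval_days,
                        ADDL=n_doses - 1, EVID=1, MDV=1, **base,
                    )
                )
            if dropped[i]:
                rec = dict(base, DROPOUT=1)
                rows.append(
                    dict(
                        ID=sid, TIME=times[event_idx[i]], DV=np.nan, AMT=np.nan,
                        II=np.nan, ADDL=np.nan, EVID=3, MDV=1, **rec,
                    )
                )
        df = pd.DataFrame(rows, columns=_COLUMNS)
        df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
        return cls(df)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        df = self.df
        for col in ("ID", "TIME", "EVID", "MDV", "DROPOUT"):
            bad = df.index[df[col].isna()].tolist()
            if bad:
                raise ValueError(f"malformed rows (missing {col}) at lines {bad}")
        obs = df[df.EVID == 0]
        bad = obs.index[obs.DV.isna() & (obs.MDV == 0)].tolist()
        if bad:
            raise ValueError(f"observation rows without DV at lines {bad}")
        for sid, g in df.groupby("ID", sort=False):
            t = g.TIME.to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError(f"non-monotone times for subject {sid}")
            gobs = g[(g.EVID == 0) & (g.MDV == 0)]
            if len(gobs) == 0 or gobs.TIME.min() != 0.0:
                raise ValueError(f"subject {sid} lacks a baseline observation at t=0")
            gdrop = g[g.EVID == 3]
            if len(gdrop) > 1:
                raise ValueError(f"subject {sid} has multiple dropout records")
            if len(gdrop) == 1:
                tdrop = float(gdrop.TIME.iloc[0])
                if (gobs.TIME >= tdrop).any():
                    raise ValueError(
                        f"subject {sid} has observations after its dropout time"
                    )

    # -- accessors ---------------------------------------------------------

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df.ID.unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def covariates(self) -> pd.DataFrame:
        """One numeric covariate row per subject (lower-case names)."""
        first = self.df.groupby("ID", sort=False).first()
        out = pd.DataFrame({k: first[v].to_numpy(dtype=float) for k, v in _COV_MAP.items()})
        return out

    def to_packed(self) -> _Packed:
        df = self.df
        obs = df[(df.EVID == 0) & (df.MDV == 0)]
        times = np.unique(obs.TIME.to_numpy(dtype=float))
        if times[0] != 0.0:
            raise ValueError("observation grid must start at t=0")
        ids = df.ID.unique()
        idx = {sid: i for i, sid in enumerate(ids)}
        n, m = len(ids), len(times)
        y = np.full((n, m), np.nan)
        rows = obs.ID.map(idx).to_numpy()
        cols = np.searchsorted(times, obs.TIME.to_numpy(dtype=float))
        if not np.allclose(times[cols], obs.TIME.to_numpy(dtype=float)):
            raise ValueError("observation times do not lie on a common visit grid")
        y[rows, cols] = obs.DV.to_numpy(dtype=float)

        dose = df[df.EVID == 1]
        amount = np.zeros(n)
        interval_h = 12.0
        for _, r in dose.iterrows():
            amount[idx[r.ID]] = float(r.AMT)
            interval_h = float(r.II) * 24.0

        dropped = np.zeros(n, dtype=bool)
        event_idx = np.full(n, -1, dtype=int)
        for _, r in df[df.EVID == 3].iterrows():
            i = idx[r.ID]
            dropped[i] = True
            j = int(np.searchsorted(times, float(r.TIME)))
            if j >= m or not np.isclose(times[j], float(r.TIME)):
                raise ValueError(
                    f"dropout time {r.TIME} of subject {r.ID} is off the visit grid"
                )
            event_idx[i] = j

        first = df.groupby("ID", sort=False).first()
        arm = first["ARM"].to_numpy()
        return _Packed(
            ids=ids,
            times=times,
            y=y,
            dose_amount=amount,
            dose_interval=interval_h,
            dropped=dropped,
            event_idx=event_idx,
            covariates=self.covariates(),
            arm=arm,
        )

    # -- I/O ---------------------------------------------------------------

    def write(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "LongitudinalDataset":
        try:
            df = pd.read_csv(path)
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"cannot parse dataset {path}: {exc}") from exc
        return cls(df)


def write_dataset(ds: LongitudinalDataset, path) -> None:
    ds.write(path)


def read_dataset(path) -> LongitudinalDataset:
    return LongitudinalDataset.read(path)
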
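"""Subject-level trial data model.

One row per randomized subject.  Times are days from randomization; the
administrative horizon of subject *j* is ``C_j = D - R_j + 1`` where ``D`` is
the common study data-cut day and ``R_j`` the randomization day.  A dataset is
partitioned into three disjoint disposition classes:

* **completer** — on randomized treatment through the first event, death, or
  the data-cut;
* **retrieved dropout (RD)** — discontinued randomized treatment but followed
  in-study to event, death, or the data-cut (an event occurring after
  treatment discontinuation still makes the subject an RD);
* **missing** — discontinued the study before the horizon with no prior event
  and no death-based completion of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, TrialDataError

__all__ = [
    "SubjectRecord",
    "TrialDataset",
    "DispositionPartition",
    "COMPLETER",
    "RETRIEVED_DROPOUT",
    "MISSING",
    "classify_disposition",
    "derive_horizons",
    "read_trial_table",
    "write_trial_table",
]

#: disposition labels
COMPLETER = "completer"
RETRIEVED_DROPOUT = "retrieved_dropout"
MISSING = "missing"

#: canonical column order; covariates are appended after these
CORE_COLUMNS = [
    "id",
    "trt",
    "R",
    "T_obs",
    "E",
    "trt_disc_day",
    "study_disc_day",
    "death_day",
]

DEFAULT_DIALECT = {c: c for c in CORE_COLUMNS}


@dataclass(frozen=True)
class SubjectRecord:
    """One randomized subject."""

    id: object
    trt: int
    R: float
    T_obs: float
    E: int
    X: tuple = ()
    trt_disc_day: float | None = None
    study_disc_day: float | None = None
    death_day: float | None = None
    C: float | None = None


@dataclass(frozen=True)
class DispositionPartition:
    """Disjoint id sets covering the randomized population."""

    completers: frozenset
    retrieved_dropouts: frozenset
    missing: frozenset

    def __post_init__(self):
        sets = (self.completers, self.retrieved_dropouts, self.missing)
        total = sum(len(s) for s in sets)
        union = frozenset().union(*sets)
        if len(union) != total:
            raise TrialDataError("disposition classes overlap")

    @property
    def n(self) -> int:
        return len(self.completers) + len(self.retrieved_dropouts) + len(self.missing)


class TrialDataset:
    """Collection of subjects sharing a common data-cut day ``D``.

    Backed by a :class:`pandas.DataFrame` with the :data:`CORE_COLUMNS` plus
    one column per baseline covariate, and a derived horizon column ``C``.
    Optional day fields use NaN for "absent".
    """

    def __init__(self, df: pd.DataFrame, D: float, covariates: Sequence[str] = ()):
        df = df.copy()
        for col in CORE_COLUMNS:
            if col not in df.columns:
                if col in ("trt_disc_day", "study_disc_day", "death_day"):
                    df[col] = np.nan
                else:
                    raise FormatError(f"required column {col!r} missing")
        self.covariates = list(covariates)
        for cov in self.covariates:
            if cov not in df.columns:
                raise FormatError(f"covariate column {cov!r} missing")
        order = CORE_COLUMNS + [c for c in self.covariates if c not in CORE_COLUMNS]
        extra = [c for c in df.columns if c not in order and c not in ("C", "D")]
        self.df = df[order + extra].reset_index(drop=True)
        self.D = float(D)
        if "C" not in self.df.columns:
            self.df["C"] = np.nan
        derive_horizons(self)
        self.validate()

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TrialDataset)
            and self.D == other.D
            and self.covariates == other.covariates
            and self.df.equals(other.df)
        )

    def copy(self) -> "TrialDataset":
        out = object.__new__(TrialDataset)
        out.df = self.df.copy()
        out.D = self.D
        out.covariates = list(self.covariates)
        return out

    def validate(self) -> None:
        df = self.df
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise TrialDataError(f"duplicate subject id {dup!r}")
        for col in ("trt", "E"):
            bad = ~df[col].isin([0, 1])
            if bad.any():
                raise TrialDataError(
                    f"row {int(np.flatnonzero(bad)[0])}: {col} must be 0 or 1"
                )
        if (df["R"] < 0).any():
            row = int(np.flatnonzero(df["R"] < 0)[0])
            raise TrialDataError(f"row {row}: negative randomization day")
        if (df["R"] > self.D).any():
            row = int(np.flatnonzero(df["R"] > self.D)[0])
            raise TrialDataError(f"row {row}: randomized after the data-cut")
        if (df["T_obs"] <= 0).any():
            row = int(np.flatnonzero(df["T_obs"] <= 0)[0])
            raise TrialDataError(f"row {row}: non-positive observed time")
        over = df["T_obs"] > df["C"]
        if over.any():
            row = int(np.flatnonzero(over)[0])
            raise TrialDataError(
                f"row {row} (id {df.loc[row, 'id']!r}): T_obs exceeds horizon C"
            )
        tdisc = df["trt_disc_day"]
        bad = tdisc.notna() & (tdisc > df["T_obs"])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TrialDataError(f"row {row}: trt_disc_day after observed time")
        sdisc = df["study_disc_day"]
        mism = sdisc.notna() & (df["E"] == 0) & (sdisc < df["C"]) & (
            ~np.isclose(df["T_obs"], np.minimum(sdisc, df["death_day"].fillna(np.inf)))
        )
        if "imputed" in df.columns:
            # post-imputation rows legitimately extend past the dropout day
            mism &= df["imputed"] != 1
        if mism.any():
            row = int(np.flatnonzero(mism)[0])
            raise TrialDataError(
                f"row {row}: censored subject not censored at study discontinuation"
            )

    # -- convenience -------------------------------------------------------
    def records(self) -> Iterable[SubjectRecord]:
        for row in self.df.itertuples(index=False):
            yield SubjectRecord(
                id=row.id,
                trt=int(row.trt),
                R=float(row.R),
                T_obs=float(row.T_obs),
                E=int(row.E),
                X=tuple(getattr(row, c) for c in self.covariates),
                trt_disc_day=None if pd.isna(row.trt_disc_day) else float(row.trt_disc_day),
                study_disc_day=None if pd.isna(row.study_disc_day) else float(row.study_disc_day),
                death_day=None if pd.isna(row.death_day) else float(row.death_day),
                C=float(row.C),
            )

    def subset(self, ids) -> "TrialDataset":
        """New dataset restricted to the given ids (order preserved)."""
        mask = self.df["id"].isin(set(ids))
        out = object.__new__(TrialDataset)
        out.df = self.df.loc[mask].reset_index(drop=True)
        out.D = self.D
        out.covariates = list(self.covariates)
        return out

    def design_matrix(self, covariates: Sequence[str] | None = None) -> np.ndarray:
        """Design matrix Z = (trt, X) as a float array."""
        covs = self.covariates if covariates is None else list(covariates)
        cols = ["trt"] + [c for c in covs if c != "trt"]
        return self.df[cols].to_numpy(dtype=float)


def derive_horizons(data: TrialDataset) -> TrialDataset:
    """Set every subject's horizon to ``C = D - R + 1`` (idempotent)."""
    if (data.df["R"] > data.D).any():
        row = int(np.flatnonzero(data.df["R"] > data.D)[0])
        raise TrialDataError(f"row {row}: randomized after the data-cut")
    data.df["C"] = data.D - data.df["R"] + 1.0
    return data


def classify_disposition(data: TrialDataset) -> DispositionPartition:
    """Split the randomized population into completers / RDs / missing.

    Missing: study discontinuation strictly before the horizon, no event, and
    no death completing follow-up.  RD: off randomized treatment before the
    end of follow-up (their outcome — event or censoring — is observed).
    Everyone else is a completer; subjects followed to death count as
    complete, and a discontinuation on/after the horizon day counts as
    followed to the cut.
    """
    df = data.df
    sdisc = df["study_disc_day"]
    if (sdisc.notna() & df["T_obs"].isna()).any():
        raise TrialDataError("subject with study_disc_day but no observed time")
    dead = df["death_day"].notna()
    missing = sdisc.notna() & (sdisc < df["C"]) & (df["E"] == 0) & ~dead
    tdisc = df["trt_disc_day"]
    off_treatment = tdisc.notna() & (tdisc < df["T_obs"])
    rd = ~missing & off_treatment
    completer = ~missing & ~rd
    ids = df["id"]
    return DispositionPartition(
        completers=frozenset(ids[completer]),
        retrieved_dropouts=frozenset(ids[rd]),
        missing=frozenset(ids[missing]),
    )


# ---------------------------------------------------------------------------
# delimited I/O


def _resolve_dialect(columns, dialect: Mapping[str, str] | None):
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    mapping = {}
    for canonical, actual in dialect.items():
        if actual in columns:
            mapping[actual] = canonical
    for required in ("id", "trt", "R", "T_obs", "E"):
        if dialect[required] not in columns:
            raise FormatError(
                f"required column {dialect[required]!r} (for {required}) not found"
            )
    return mapping


def read_trial_table(
    path,
    D: float | None = None,
    dialect: Mapping[str, str] | None = None,
    covariates: Sequence[str] = (),
    sep: str = ",",
) -> TrialDataset:
    """Read a delimited trial file into a validated :class:`TrialDataset`.

    ``dialect`` maps canonical field names to the file's column names; ``D``
    may be omitted when the file carries a ``D`` column (common value).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    mapping = _resolve_dialect(raw.columns, dialect)
    df = raw.rename(columns=mapping)
    if D is None:
        if "D" not in df.columns:
            raise FormatError("data-cut day D not given and no 'D' column in file")
        dvals = df["D"].unique()
        if len(dvals) > 1:
            raise TrialDataError("subjects do not share a common data-cut D")
        D = float(dvals[0]) if len(dvals) == 1 else 0.0
    for col in ("trt", "R", "T_obs", "E", "trt_disc_day", "study_disc_day", "death_day"):
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
                row = int(np.flatnonzero(bad)[0]) if bad.any() else "?"
                raise FormatError(f"non-numeric value in column {col!r} at row {row}") from exc
    return TrialDataset(df, D=D, covariates=covariates)


def write_trial_table(data: TrialDataset, path, sep: str = ",") -> None:
    """Write the dataset (plus its common ``D``) back to delimited text."""
    out = data.df.copy()
    out["D"] = data.D
    out.to_csv(path, sep=sep, index=False)
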
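"""Reading, validation and per-study summaries of pooled individual patient data.

The expected input is a delimited text file (comma, semicolon or tab
separated) with one row per patient and three mandatory columns:

``Study``
    study label (author name or numeric code; treated as an opaque label),
``test.results``
    the continuous index-test value,
``disease``
    reference-standard disease status coded 0/1.

Every other column is treated as a patient-level covariate and typed
automatically as continuous or categorical.  Missing values are handled by
complete-case analysis per variable: a record missing a covariate is removed
only from analyses that use that covariate and kept everywhere else.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mandatory column names in input files, in the order (study, test, disease)
RESERVED_COLUMNS = ("Study", "test.results", "disease")

#: internal column names used after loading
STUDY_LABEL, STUDY_ID, TEST_RESULT, DISEASE = (
    "study_label",
    "study_id",
    "test_result",
    "disease",
)
_INTERNAL = (STUDY_LABEL, STUDY_ID, TEST_RESULT, DISEASE)

SEPARATORS: Mapping[str, str] = {"comma": ",", "semicolon": ";", "tab": "\t"}

DEFAULT_MISSING_TOKENS = ("", "NA")

#: numeric covariates with at most this many distinct values default to categorical
DEFAULT_CATEGORICAL_CUTOFF = 10


class SchemaError(ValueError):
    """A mandatory column is missing or a column name collides with a reserved one."""


class DialectError(ValueError):
    """The file parsed into a single column; the separator is probably wrong."""


class ParseError(ValueError):
    """A cell could not be interpreted (e.g. non-numeric test result)."""


class ValidationError(ValueError):
    """The parsed table violates the data contract (e.g. disease not in {0, 1})."""


class EmptyAnalysisError(ValueError):
    """No rows remain for the requested analysis."""


@dataclass(frozen=True)
class IPDDataset:
    """Validated pooled patient-level table.

    ``frame`` holds one row per patient with internal columns ``study_label``,
    ``study_id`` (sequential 1..K by first appearance), ``test_result``,
    ``disease`` plus one column per covariate.  ``covariate_types`` maps each
    covariate name to ``"continuous"`` or ``"categorical"``.
    ``flagged_studies`` lists study ids lacking one of the two disease classes;
    these are kept in the data but excluded from per-study accuracy analyses.
    """

    frame: pd.DataFrame
    covariate_types: Mapping[str, str] = field(default_factory=dict)
    flagged_studies: tuple[int, ...] = ()

    @property
    def covariates(self) -> list[str]:
        return list(self.covariate_types)

    @property
    def study_ids(self) -> list[int]:
        return sorted(self.frame[STUDY_ID].unique().tolist())

    @property
    def n_studies(self) -> int:
        return self.frame[STUDY_ID].nunique()

    @property
    def analyzable_study_ids(self) -> list[int]:
        """Study ids with at least one diseased and one nondiseased record."""
        return [s for s in self.study_ids if s not in self.flagged_studies]

    def __len__(self) -> int:
        return len(self.frame)

    def study_frame(self, study_id: int) -> pd.DataFrame:
        sub = self.frame[self.frame[STUDY_ID] == study_id]
        if sub.empty:
            raise KeyError(f"unknown study_id {study_id}")
        return sub

    def test_values(self, study_id: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (diseased, nondiseased) test-result arrays, NaNs dropped.

        With ``study_id=None`` the pooled data across all studies is used.
        """
        sub = self.frame if study_id is None else self.study_frame(study_id)
        sub = sub.dropna(subset=[TEST_RESULT, DISEASE])
        d = sub.loc[sub[DISEASE] == 1, TEST_RESULT].to_numpy(float)
        nd = sub.loc[sub[DISEASE] == 0, TEST_RESULT].to_numpy(float)
        return d, nd

    def study_labels(self) -> dict[int, str]:
        pairs = self.frame[[STUDY_ID, STUDY_LABEL]].drop_duplicates()
        return dict(zip(pairs[STUDY_ID], pairs[STUDY_LABEL].astype(str)))


@dataclass(frozen=True)
class StudySummary:
    """Descriptive statistics of one primary study."""

    study_id: int
    study_label: str
    n_total: int
    n_diseased: int
    prevalence: float
    #: test-result mean/SD by disease group: {"diseased": (mean, sd), ...}
    test_by_group: Mapping[str, tuple[float, float]]
    #: covariate name -> statistics dict (see :func:`summarize_studies`)
    covariate_stats: Mapping[str, Mapping[str, object]]


def _assign_study_ids(labels: pd.Series) -> pd.Series:
    codes, _ = pd.factorize(labels)  # factorize preserves first-appearance order
    return pd.Series(codes + 1, index=labels.index, name=STUDY_ID)


def _type_covariate(col: pd.Series, cutoff: int) -> str:
    numeric = pd.to_numeric(col, errors="coerce")
    observed = col.notna()
    if observed.any() and numeric[observed].isna().any():
        return "categorical"
    return "categorical" if numeric.dropna().nunique() <= cutoff else "continuous"


def _flag_single_class_studies(frame: pd.DataFrame) -> tuple[int, ...]:
    flagged = []
    for sid, sub in frame.groupby(STUDY_ID):
        classes = set(sub[DISEASE].dropna().unique())
        if classes != {0, 1}:
            flagged.append(int(sid))
    if flagged:
        logger.warning(
            "studies %s have a single disease class and are excluded from "
            "per-study accuracy analyses",
            flagged,
        )
    return tuple(flagged)


def from_frame(
    df: pd.DataFrame,
    categorical_cutoff: int = DEFAULT_CATEGORICAL_CUTOFF,
    covariate_types: Mapping[str, str] | None = None,
) -> IPDDataset:
    """Validate a raw table using the input-file column contract.

    ``df`` must carry the reserved columns ``Study``, ``test.results`` and
    ``disease``; all other columns become covariates.  ``covariate_types`` can
    override the automatic continuous/categorical typing per column.
    """
    for col in RESERVED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} is missing")
    covariate_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    for c in covariate_cols:
        if c in _INTERNAL:
            raise SchemaError(f"covariate name {c!r} collides with a reserved internal name")

    test = pd.to_numeric(df["test.results"], errors="coerce")
    bad = test.isna() & df["test.results"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric entry {df['test.results'].iloc[row]!r} in 'test.results' at data row {row + 1}"
        )

    disease = pd.to_numeric(df["disease"], errors="coerce")
    observed = disease.dropna()
    if not set(observed.unique()) <= {0, 1}:
        offending = sorted(set(observed.unique()) - {0, 1})
        raise ValidationError(
            f"'disease' must only contain 0 or 1; found {offending}"
        )
    if df["disease"].notna().sum() != observed.size:
        raise ValidationError("'disease' contains entries that are neither 0, 1 nor missing")

    out = pd.DataFrame(
        {
            STUDY_LABEL: df["Study"].astype(str),
            STUDY_ID: _assign_study_ids(df["Study"]),
            TEST_RESULT: test,
            DISEASE: disease,  # float with NaN for missing; values validated above
        },
        index=df.index,
    )

    types: dict[str, str] = {}
    for c in covariate_cols:
        declared = (covariate_types or {}).get(c)
        if declared is not None:
            if declared not in ("continuous", "categorical"):
                raise ValidationError(f"covariate type for {c!r} must be continuous or categorical")
            types[c] = declared
        else:
            types[c] = _type_covariate(df[c], categorical_cutoff)
        if types[c] == "continuous":
            out[c] = pd.to_numeric(df[c], errors="coerce")
        else:
            out[c] = df[c]

    out = out.reset_index(drop=True)
    return IPDDataset(frame=out, covariate_types=types, flagged_studies=_flag_single_class_studies(out))


def load_ipd_csv(
    path,
    separator: str = "comma",
    categorical_cutoff: int = DEFAULT_CATEGORICAL_CUTOFF,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    covariate_types: Mapping[str, str] | None = None,
) -> IPDDataset:
    """Load a delimited IPD file and validate it.

    Parameters
    ----------
    path : str or Path
        File with a header row and the three mandatory columns.
    separator : {"comma", "semicolon", "tab"}
        Field separator of the file.
    categorical_cutoff : int
        Numeric covariates with at most this many distinct values are typed
        categorical.
    missing_tokens : sequence of str
        Cell contents recognized as missing, in addition to empty cells.
    covariate_types : mapping, optional
        Per-column override of the automatic covariate typing.
    """
    if separator not in SEPARATORS:
        raise ValueError(f"separator must be one of {sorted(SEPARATORS)}, got {separator!r}")
    df = pd.read_csv(
        path,
        sep=SEPARATORS[separator],
        na_values=list(missing_tokens),
        keep_default_na=False,
        skipinitialspace=True,
    )
    if df.shape[1] == 1:
        others = sorted(set(SEPARATORS) - {separator})
        raise DialectError(
            f"file parsed into a single column with separator={separator!r}; "
            f"try one of {others}"
        )
    return from_frame(df, categorical_cutoff=categorical_cutoff, covariate_types=covariate_types)


def head_or_all(data: IPDDataset, mode: str = "head") -> pd.DataFrame:
    """Return the first six rows (``mode="head"``) or the full table (``"all"``)."""
    if mode == "head":
        return data.frame.head(6)
    if mode == "all":
        return data.frame
    raise ValueError(f"mode must be 'head' or 'all', got {mode!r}")


def _continuous_stats(col: pd.Series) -> dict[str, object]:
    obs = pd.to_numeric(col, errors="coerce").dropna()
    return {
        "type": "continuous",
        "mean": float(obs.mean()) if len(obs) else np.nan,
        "sd": float(obs.std(ddof=1)) if len(obs) > 1 else np.nan,
        "min": float(obs.min()) if len(obs) else np.nan,
        "max": float(obs.max()) if len(obs) else np.nan,
        "n_missing": int(col.isna().sum()),
    }


def _categorical_stats(col: pd.Series) -> dict[str, object]:
    obs = col.dropna()
    counts = obs.value_counts()
    total = int(counts.sum())
    levels = {
        str(level): {"count": int(n), "percent": 100.0 * n / total if total else np.nan}
        for level, n in counts.items()
    }
    return {"type": "categorical", "levels": levels, "n_missing": int(col.isna().sum())}


def summarize_studies(data: IPDDataset) -> list[StudySummary]:
    """Per-study descriptive statistics, in study_id order.

    Covariate statistics use the observed values of that covariate within the
    study (per-variable complete cases); the number of missing entries is
    reported alongside.
    """
    summaries: list[StudySummary] = []
    for sid in data.study_ids:
        sub = data.study_frame(sid)
        disease = sub[DISEASE].dropna()
        n_total = int(len(sub))
        n_diseased = int((disease == 1).sum())
        by_group = {}
        for name, mask in (("diseased", sub[DISEASE] == 1), ("nondiseased", sub[DISEASE] == 0)):
            vals = sub.loc[mask, TEST_RESULT].dropna()
            by_group[name] = (
                float(vals.mean()) if len(vals) else np.nan,
                float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            )
        cov_stats = {}
        for c, kind in data.covariate_types.items():
            cov_stats[c] = (
                _continuous_stats(sub[c]) if kind == "continuous" else _categorical_stats(sub[c])
            )
        summaries.append(
            StudySummary(
                study_id=int(sid),
                study_label=str(sub[STUDY_LABEL].iloc[0]),
                n_total=n_total,
                n_diseased=n_diseased,
                prevalence=n_diseased / n_total if n_total else np.nan,
                test_by_group=by_group,
                covariate_stats=cov_stats,
            )
        )
    return summaries


def summary_table(data: IPDDataset) -> pd.DataFrame:
    """Flat, CSV-exportable version of :func:`summarize_studies`."""
    rows = []
    for s in summarize_studies(data):
        row: dict[str, object] = {
            "study_id": s.study_id,
            "study": s.study_label,
            "n": s.n_total,
            "n_diseased": s.n_diseased,
            "prevalence": s.prevalence,
            "test_mean_diseased": s.test_by_group["diseased"][0],
            "test_sd_diseased": s.test_by_group["diseased"][1],
            "test_mean_nondiseased": s.test_by_group["nondiseased"][0],
            "test_sd_nondiseased": s.test_by_group["nondiseased"][1],
        }
        for c, st in s.covariate_stats.items():
            if st["type"] == "continuous":
                row[f"{c}_mean"] = st["mean"]
                row[f"{c}_sd"] = st["sd"]
            else:
                for level, lv in st["levels"].items():
                    row[f"{c}_{level}_pct"] = lv["percent"]
            row[f"{c}_missing"] = st["n_missing"]
        rows.append(row)
    return pd.DataFrame(rows)


def complete_case_subset(data: IPDDataset, required_columns: Iterable[str]) -> IPDDataset:
    """Rows with no missing value in any required column.

    Rows missing only in non-required columns are retained; study ids are
    preserved (no renumbering), so results remain attributable to the original
    studies.  A study losing all of its rows triggers a warning; losing all
    rows overall raises :class:`EmptyAnalysisError`.
    """
    required = list(required_columns)
    for c in required:
        if c not in data.frame.columns:
            raise KeyError(f"required column {c!r} not in dataset")
    kept = data.frame.dropna(subset=required)
    if kept.empty:
        raise EmptyAnalysisError(f"no rows remain after complete-case filtering on {required}")
    lost = sorted(set(data.frame[STUDY_ID]) - set(kept[STUDY_ID]))
    if lost:
        warnings.warn(f"studies {lost} lost all rows under complete-case filtering on {required}")
    return IPDDataset(
        frame=kept.reset_index(drop=True),
        covariate_types=data.covariate_types,
        flagged_studies=_flag_single_class_studies(kept),
    )
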
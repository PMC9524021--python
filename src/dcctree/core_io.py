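"""Domain types, file I/O, the packaged DMN parcellation, cohort filtering
and optional signal conditioning.

The pipeline ingests already-extracted ROI time series: delimited text with a
header row of ROI abbreviations and one row per fMRI volume.  Phenotype tables
are CSV with the column names used by the ABIDE phenotypic releases
(``func_mean_fd``, ``func_perc_fd``, ADOS scales, ...).  No image handling
happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = [
    "subject_id", "group", "age", "sex", "iq", "site",
    "func_mean_fd", "func_perc_fd",
    "ados_total", "ados_comm", "ados_social", "ados_stereo_behav",
]
ADOS_COLUMNS = ["ados_total", "ados_comm", "ados_social", "ados_stereo_behav"]

_GROUP_ALIASES = {
    "asd": "ASD", "autism": "ASD", "1": "ASD",
    "td": "TD", "control": "TD", "typical": "TD", "2": "TD", "0": "TD",
}


class ParseError(ValueError):
    """A delimited input file violates the expected layout."""


@dataclass(frozen=True)
class ROIDefinition:
    """One spherical region of interest in MNI space."""

    index: int
    name: str
    abbrev: str
    subsystem: str  # core | dMPFC | MTL
    mni_x: float
    mni_y: float
    mni_z: float
    radius: float = 10.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"ROI {self.abbrev}: radius must be positive")


@dataclass(frozen=True)
class Parcellation:
    """An ordered set of ROI definitions; defines node order for all matrices."""

    rois: tuple[ROIDefinition, ...]

    def __post_init__(self) -> None:
        abbrevs = [r.abbrev for r in self.rois]
        if len(set(abbrevs)) != len(abbrevs):
            raise ValueError("duplicate ROI abbreviations in parcellation")
        if [r.index for r in self.rois] != list(range(1, len(self.rois) + 1)):
            raise ValueError("ROI indices must be consecutive 1..N")

    @property
    def n(self) -> int:
        return len(self.rois)

    @property
    def abbrevs(self) -> list[str]:
        return [r.abbrev for r in self.rois]


@dataclass
class SubjectTimeSeries:
    """One subject's N x T ROI signal matrix.

    Rows follow the parcellation order; ``tr`` is the sampling interval in
    seconds; ``demeaned`` records whether each row has been mean-centred.
    """

    subject_id: str
    data: np.ndarray  # (N, T)
    tr: float = 2.0
    demeaned: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D (N, T) matrix")
        if self.data.shape[1] < 2:
            raise ValueError("need at least T=2 time points")
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values in series")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def t_len(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class PhenotypeRecord:
    subject_id: str
    group: str  # "ASD" | "TD"
    age: float
    sex: str
    iq: float
    site: str
    func_mean_fd: float
    func_perc_fd: float
    ados_total: float | None = None
    ados_comm: float | None = None
    ados_social: float | None = None
    ados_stereo_behav: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("ASD", "TD"):
            raise ValueError(f"{self.subject_id}: group must be ASD or TD, got {self.group!r}")
        if not np.isnan(self.func_perc_fd) and not (0 <= self.func_perc_fd <= 100):
            raise ValueError(
                f"{self.subject_id}: func_perc_fd={self.func_perc_fd} outside [0, 100]"
            )

    def ados(self, scale: str) -> float | None:
        value = getattr(self, f"ados_{scale.lower()}")
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        return value


@dataclass
class Cohort:
    """Phenotype records plus (optionally) where each subject's series lives."""

    records: list[PhenotypeRecord]
    series_paths: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def subset(self, subject_ids: Sequence[str]) -> "Cohort":
        keep = set(subject_ids)
        return Cohort(
            records=[r for r in self.records if r.subject_id in keep],
            series_paths={k: v for k, v in self.series_paths.items() if k in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({c: getattr(r, c) for c in PHENOTYPE_COLUMNS})
        return pd.DataFrame(rows).set_index("subject_id")


def load_dmn_parcellation() -> Parcellation:
    """Load the packaged 18-ROI default-mode-network parcellation.

    The fixture lists the 18 spherical ROIs (10 mm radius) of the core,
    dMPFC and MTL subsystems with their MNI centroid coordinates.
    """
    ref = resources.files("dcctree.data") / "dmn_parcellation.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    expected = {"index", "name", "abbrev", "subsystem", "mni_x", "mni_y", "mni_z", "radius"}
    if set(df.columns) != expected or len(df) == 0:
        raise RuntimeError("packaged parcellation fixture is corrupted")
    rois = tuple(
        ROIDefinition(
            index=int(row["index"]), name=row["name"], abbrev=row["abbrev"],
            subsystem=row["subsystem"], mni_x=float(row["mni_x"]),
            mni_y=float(row["mni_y"]), mni_z=float(row["mni_z"]),
            radius=float(row["radius"]),
        )
        for _, row in df.iterrows()
    )
    return Parcellation(rois=rois)


def _read_delimited(path: Path | str) -> pd.DataFrame:
    # sniff tab vs comma from the header line
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep)


def read_timeseries(
    path: Path | str,
    parcellation: Parcellation,
    subject_id: str | None = None,
    tr: float = 2.0,
) -> SubjectTimeSeries:
    """Read one subject's ROI table (rows = time points, columns = ROIs).

    Columns are matched to the parcellation BY NAME, so column order in the
    file is irrelevant; missing or non-numeric columns raise ``ParseError``.
    """
    path = Path(path)
    df = _read_delimited(path)
    missing = [a for a in parcellation.abbrevs if a not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing ROI column(s): {missing}")
    extra = [c for c in df.columns if c not in parcellation.abbrevs]
    if extra:
        raise ParseError(f"{path}: unexpected column(s): {extra}")
    if len(df) < 2:
        raise ParseError(f"{path}: need at least 2 time points, got {len(df)}")
    try:
        mat = df[parcellation.abbrevs].to_numpy(dtype=float).T
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric cell in time-series table: {exc}") from exc
    if not np.isfinite(mat).all():
        raise ParseError(f"{path}: missing or non-finite values in time-series table")
    return SubjectTimeSeries(
        subject_id=subject_id or path.stem, data=mat, tr=tr, demeaned=False
    )


def write_timeseries(ts: SubjectTimeSeries, path: Path | str,
                     parcellation: Parcellation, sep: str = "\t") -> None:
    df = pd.DataFrame(ts.data.T, columns=parcellation.abbrevs)
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_phenotype(path: Path | str) -> Cohort:
    """Read a phenotype CSV into a validated :class:`Cohort`.

    Empty ADOS cells are kept as explicitly-missing values (None); group
    labels are normalized to ASD / TD.
    """
    path = Path(path)
    df = _read_delimited(path)
    required = [c for c in PHENOTYPE_COLUMNS if c not in ADOS_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: phenotype table missing column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        group_raw = str(row["group"]).strip()
        group = _GROUP_ALIASES.get(group_raw.lower(), group_raw.upper())
        ados = {}
        for c in ADOS_COLUMNS:
            v = row.get(c, np.nan)
            ados[c] = None if pd.isna(v) else float(v)
        records.append(
            PhenotypeRecord(
                subject_id=str(row["subject_id"]),
                group=group,
                age=float(row["age"]),
                sex=str(row["sex"]),
                iq=float(row["iq"]),
                site=str(row["site"]),
                func_mean_fd=float(row["func_mean_fd"]),
                func_perc_fd=float(row["func_perc_fd"]),
                **ados,
            )
        )
    return Cohort(records=records)


def write_phenotype(cohort: Cohort, path: Path | str) -> None:
    cohort.to_frame().to_csv(path)


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusion thresholds for cohort selection.

    Defaults follow the study's criteria: mean framewise displacement below
    0.2 mm, fewer than 25% of volumes with FD > 0.2 mm, IQ above 75, and
    sites retained only when, after the other criteria, each diagnostic group
    still has strictly more than ``min_per_site_group`` subjects.
    """

    max_mean_fd: float = 0.2
    max_perc_fd: float = 25.0
    min_iq: float = 75.0
    min_per_site_group: int = 3


@dataclass
class FilterReport:
    excluded: dict[str, list[str]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.excluded.items()}


def filter_cohort(
    cohort: Cohort,
    thresholds: FilterThresholds | None = None,
    return_report: bool = False,
) -> Cohort | tuple[Cohort, FilterReport]:
    """Apply motion / IQ / site-size inclusion criteria.

    Subject-level criteria are applied first; the site-size rule last, on the
    survivors.  Records with a missing required field (age, IQ, motion) are
    excluded and logged — those criteria cannot be evaluated otherwise.
    Idempotent: filtering an already-filtered cohort is the identity.
    """
    th = thresholds or FilterThresholds()
    report = FilterReport(excluded={
        "missing_field": [], "mean_fd": [], "perc_fd": [], "iq": [], "site_size": [],
    })
    survivors: list[PhenotypeRecord] = []
    for r in cohort.records:
        if any(np.isnan(v) for v in (r.age, r.iq, r.func_mean_fd, r.func_perc_fd)):
            report.excluded["missing_field"].append(r.subject_id)
        elif not r.func_mean_fd < th.max_mean_fd:
            report.excluded["mean_fd"].append(r.subject_id)
        elif not r.func_perc_fd < th.max_perc_fd:
            report.excluded["perc_fd"].append(r.subject_id)
        elif not r.iq > th.min_iq:
            report.excluded["iq"].append(r.subject_id)
        else:
            survivors.append(r)

    # site rule: keep sites with > min_per_site_group survivors in EACH group
    by_site: dict[str, dict[str, int]] = {}
    for r in survivors:
        by_site.setdefault(r.site, {}).setdefault(r.group, 0)
        by_site[r.site][r.group] += 1
    good_sites = {
        s for s, g in by_site.items()
        if all(g.get(grp, 0) > th.min_per_site_group for grp in ("ASD", "TD"))
    }
    final = []
    for r in survivors:
        if r.site in good_sites:
            final.append(r)
        else:
            report.excluded["site_size"].append(r.subject_id)

    for crit, count in report.counts().items():
        if count:
            logger.info("filter_cohort: excluded %d subject(s) by %s", count, crit)
    if not final:
        logger.warning("filter_cohort: no subjects survive the criteria")
    out = cohort.subset([r.subject_id for r in final])
    return (out, report) if return_report else out


def bandpass_demean(
    ts: SubjectTimeSeries, low: float = 0.01, high: float = 0.1, order: int = 4
) -> SubjectTimeSeries:
    """Zero-phase band-pass filter each ROI series, then mean-centre it.

    Uses a Butterworth design applied forward-backward (``sosfiltfilt``), so
    the pass band is distortion-free in phase.  ``low``/``high`` are in Hz and
    must sit inside (0, Nyquist) for the series' sampling interval.
    """
    nyq = 0.5 / ts.tr
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz infeasible for tr={ts.tr}s (Nyquist {nyq:.4g} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    filtered = filtered - filtered.mean(axis=1, keepdims=True)
    return replace(ts, data=filtered, demeaned=True)
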
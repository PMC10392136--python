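"""Data model and file formats for the breast-cancer proteome pipeline.

All quantitative omics layers live in a single container, :class:`OmicsMatrix`:
a features x samples table of log2 abundances with explicit missing values
(``NaN`` internally, the literal token ``NA`` on disk).  The mutation layer is
the one exception — a binary presence/absence matrix with no missing entries.

Sample identity is deliberately opaque at the matrix level: which column is
which cell line, replicate group or batch is recorded only in
:class:`SampleAnnotation`, so replicate-level (4 columns per line) and
cell-line-averaged (1 column per line) matrices flow through the same code.

File dialects
-------------
* matrix TSV      — first column feature id, header row sample ids, ``NA`` missing
* annotation TSV  — columns sample_id, cell_line, subtype, tnbc, replicate_group,
                    replicate_type, batch
* drug response   — matrix TSV, rows cell lines, columns drugs (log10 IC50, molar)
* complex catalog — long TSV with columns complex_id, feature_id
* pathways        — GMT (name, description, tab-separated member ids)
* time course     — matrix TSV whose sample ids encode ``line|drug|time|rep``,
                    plus a small TSV mapping cell line to TNBC status
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("bcproteodyn")

SUBTYPES = ("basal_a", "basal_b", "luminal", "her2")
REPLICATE_TYPES = ("biological", "technical")
MISSING_TOKEN = "NA"

#: canonical perturbation sampling times, hours after treatment
TIME_POINTS_H = (0.0, 4.0, 12.0, 24.0, 48.0, 72.0)


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """One omics layer: features x samples, log2 abundance (or 0/1 mutations).

    Parameters
    ----------
    layer_name
        Free-text tag, e.g. ``"protein"``, ``"transcript"``, ``"mutation"``,
        ``"rppa"``.  A layer named ``"mutation"`` is validated as binary and
        complete; all other layers are validated as finite-where-observed.
    values
        DataFrame indexed by feature id with sample-id columns.  Missing
        entries are ``NaN``.
    """

    layer_name: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        for name, labels in (("feature", idx), ("sample", cols)):
            if labels.has_duplicates:
                dupes = labels[labels.duplicated()].unique().tolist()
                raise FormatError(f"duplicate {name} ids: {dupes[:5]}")
        if len(idx) == 0:
            raise FormatError("no features")
        vals = self.values.to_numpy(dtype=float)
        if self.layer_name == "mutation":
            if np.isnan(vals).any():
                raise FormatError("mutation layer must have no missing values")
            if not np.isin(vals, (0.0, 1.0)).all():
                raise FormatError("mutation layer must contain only 0/1")
        else:
            observed = vals[~np.isnan(vals)]
            if not np.isfinite(observed).all():
                raise FormatError(
                    f"layer {self.layer_name!r}: non-finite observed values"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_fraction(self) -> float:
        """Fraction of missing cells in the whole matrix."""
        return float(self.values.isna().to_numpy().mean())

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.layer_name, self.values.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.layer_name, self.values.loc[list(feature_ids)])


@dataclass
class SampleAnnotation:
    """Per-sample metadata joining opaque sample ids to cell-line structure."""

    table: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("cell_line", "subtype", "tnbc", "replicate_group",
                "replicate_type", "batch")

    def __post_init__(self) -> None:
        t = self.table
        missing_cols = [c for c in self.REQUIRED if c not in t.columns]
        if missing_cols:
            raise FormatError(f"annotation missing columns: {missing_cols}")
        if t.index.has_duplicates:
            raise FormatError("duplicate sample ids in annotation")
        bad_sub = set(t["subtype"]) - set(SUBTYPES)
        if bad_sub:
            raise FormatError(f"unknown subtype token(s): {sorted(bad_sub)}")
        bad_rt = set(t["replicate_type"]) - set(REPLICATE_TYPES)
        if bad_rt:
            raise FormatError(f"unknown replicate_type token(s): {sorted(bad_rt)}")
        groups = t["replicate_group"].astype(int)
        if ((groups < 1) | (groups > 4)).any():
            raise FormatError("replicate_group must be in 1..4")
        self.table = t.assign(
            replicate_group=groups, tnbc=t["tnbc"].astype(bool)
        )
        # TNBC status is a property of the cell line, not of the sample
        per_line = self.table.groupby("cell_line")["tnbc"].nunique()
        inconsistent = per_line[per_line > 1]
        if len(inconsistent):
            raise FormatError(
                f"tnbc flag inconsistent within cell line(s): "
                f"{list(inconsistent.index)[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def require_samples(self, sample_ids) -> None:
        """Error if any of ``sample_ids`` lacks an annotation row."""
        unknown = [s for s in sample_ids if s not in self.table.index]
        if unknown:
            raise FormatError(
                f"{len(unknown)} sample(s) absent from annotation, "
                f"e.g. {unknown[:5]}"
            )

    def for_samples(self, sample_ids) -> pd.DataFrame:
        self.require_samples(sample_ids)
        return self.table.loc[list(sample_ids)]

    def tnbc_lines(self) -> list[str]:
        t = self.table.drop_duplicates("cell_line")
        return sorted(t.loc[t["tnbc"], "cell_line"])


@dataclass
class DrugResponseTable:
    """Cell line x drug response matrix, log10 IC50 (molar); missing allowed."""

    values: pd.DataFrame  # index cell_line, columns drug

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise FormatError("duplicate cell line or drug ids in drug response")
        vals = self.values.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if not np.isfinite(observed).all():
            raise FormatError("non-finite drug response values")

    @property
    def drugs(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.index)

    def response(self, drug: str) -> pd.Series:
        """Observed responses for one drug (missing lines dropped)."""
        return self.values[drug].dropna()


class ComplexCatalog(dict):
    """Mapping complex_id -> frozenset of member feature ids (size >= 1)."""

    def __init__(self, members: Mapping[str, frozenset] | None = None):
        super().__init__()
        for cid, mem in (members or {}).items():
            mem = frozenset(mem)
            if not mem:
                raise FormatError(f"complex {cid!r} has no members")
            self[cid] = mem


class PathwayAnnotation(dict):
    """Mapping pathway_id -> frozenset of member feature ids (GMT semantics)."""

    def __init__(self, members: Mapping[str, frozenset] | None = None):
        super().__init__()
        for pid, mem in (members or {}).items():
            mem = frozenset(mem)
            if not mem:
                raise FormatError(f"pathway {pid!r} has no members")
            self[pid] = mem


@dataclass
class TimeCourseExperiment:
    """Drug-perturbation proteome indexed by (cell line, drug, time h, replicate).

    ``values`` carries a 4-level column MultiIndex
    ``(cell_line, drug, time_h, replicate)``; ``tnbc`` maps each cell line to
    its TNBC status.  Time 0 is the pre-treatment baseline and must be present.
    """

    values: pd.DataFrame
    tnbc: dict[str, bool]

    def __post_init__(self) -> None:
        cols = self.values.columns
        if cols.nlevels != 4:
            raise FormatError(
                "time-course columns must be (cell_line, drug, time_h, replicate)"
            )
        self.values.columns = cols.set_names(
            ["cell_line", "drug", "time_h", "replicate"]
        )
        times = self.time_points_h
        if list(times) != sorted(set(times)):
            raise FormatError("time points must be strictly increasing")
        if 0.0 not in times:
            raise FormatError("time 0 (pre-treatment baseline) is required")
        unknown = set(self.cell_lines) - set(self.tnbc)
        if unknown:
            raise FormatError(f"cell line(s) without tnbc flag: {sorted(unknown)}")

    @property
    def cell_lines(self) -> list[str]:
        return sorted(set(self.values.columns.get_level_values("cell_line")))

    @property
    def drugs(self) -> list[str]:
        return sorted(set(self.values.columns.get_level_values("drug")))

    @property
    def time_points_h(self) -> list[float]:
        return sorted(set(self.values.columns.get_level_values("time_h")))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def tnbc_lines(self) -> list[str]:
        return sorted(l for l, flag in self.tnbc.items() if flag)

    def non_tnbc_lines(self) -> list[str]:
        return sorted(l for l, flag in self.tnbc.items() if not flag)

    def condition(self, cell_line: str, drug: str, time_h: float) -> pd.DataFrame:
        """Replicate columns for one (line, drug, time) condition."""
        return self.values.loc[:, (cell_line, drug, time_h)]


@dataclass
class RunConfig:
    """All thresholds and grids of a pipeline run; fully determines outputs.

    Defaults follow the published analysis where it states a value; the rest
    are the package's own documented choices.
    """

    seed: int = 0
    # qc
    max_missing_fraction: float = 0.9
    outlier_z_threshold: float = 3.0
    cv_n_bins: int = 3
    # differential expression
    de_p_threshold: float = 0.05
    de_fc_up: float = 1.5
    de_fc_down: float = 0.67
    signature_n: int = 38
    equal_var_ttest: bool = True
    # complexes
    min_co_observed: int = 3
    top_n_pairs: int = 10
    # elastic net (see enpredict.ENConfig for the full grid)
    en_preset: str = "fast"
    # dynamics
    ic50_tau: float = 0.7
    ic50_max_missing_timepoints: int = 1
    fuzzifier_m: float = 2.0
    n_clusters: int = 6
    monotone_rho: float = 0.8
    trend_fc_threshold: float = 2.0
    trend_p_threshold: float = 0.05
    pdp_frac_threshold: float = 0.6
    intersect_drugs: bool = False
    pathway_tnbc_min: float = 3 / 5
    pathway_non_tnbc_min: float = 2 / 4

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN],
                     keep_default_na=False, dtype=str)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no features")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str),
                       dtype=float)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            ) from None
    return out


def read_matrix(path, layer_name: str, linear_input: bool = False) -> OmicsMatrix:
    """Read a features x samples TSV (first column feature id, ``NA`` missing).

    Intensity layers are stored and processed in log2 throughout the
    pipeline; declare ``linear_input=True`` to log2-transform linear-scale
    intensities at read time (values must be positive).
    """
    df = _read_tsv_matrix(path)
    if linear_input:
        if layer_name == "mutation":
            raise FormatError("mutation layer cannot be linear-scale")
        if (df <= 0).any().any():
            raise FormatError(f"{path}: non-positive linear intensities")
        df = np.log2(df)
    return OmicsMatrix(layer_name, df)


def write_matrix(m: OmicsMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.6f")


def read_annotation(path) -> SampleAnnotation:
    t = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "tnbc" in t.columns:
        t["tnbc"] = t["tnbc"].str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        if t["tnbc"].isna().any():
            raise FormatError(f"{path}: unparseable tnbc flag")
    return SampleAnnotation(t)


def write_annotation(ann: SampleAnnotation, path) -> None:
    t = ann.table.copy()
    t.index.name = "sample_id"
    t.to_csv(path, sep="\t")


def read_drug_response(path) -> DrugResponseTable:
    return DrugResponseTable(_read_tsv_matrix(path))


def write_drug_response(r: DrugResponseTable, path) -> None:
    df = r.values.copy()
    df.index.name = "cell_line"
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.6f")


def read_gmt(path) -> PathwayAnnotation:
    """Read GMT: one pathway per line — name, description, then member ids."""
    members: dict[str, frozenset] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: GMT line needs name, desc, members")
        name, _desc, *mem = parts
        mem = [m for m in mem if m]
        if name in members:
            raise FormatError(f"{path}:{ln}: duplicate pathway {name!r}")
        members[name] = frozenset(mem)
    return PathwayAnnotation(members)


def write_gmt(pathways: PathwayAnnotation, path) -> None:
    lines = [
        "\t".join([pid, "na", *sorted(mem)]) for pid, mem in sorted(pathways.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_complexes(path) -> ComplexCatalog:
    """Read a long-format catalog TSV with columns complex_id, feature_id."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    if list(t.columns[:2]) != ["complex_id", "feature_id"]:
        raise FormatError(
            f"{path}: expected columns complex_id, feature_id; got {list(t.columns)}"
        )
    members: dict[str, set] = {}
    for cid, fid in zip(t["complex_id"], t["feature_id"]):
        members.setdefault(cid, set()).add(fid)
    return ComplexCatalog({cid: frozenset(m) for cid, m in members.items()})


def write_complexes(cat: ComplexCatalog, path) -> None:
    rows = [(cid, fid) for cid, mem in sorted(cat.items()) for fid in sorted(mem)]
    pd.DataFrame(rows, columns=["complex_id", "feature_id"]).to_csv(
        path, sep="\t", index=False
    )


_TC_SEP = "|"


def write_timecourse(tc: TimeCourseExperiment, matrix_path, lines_path) -> None:
    """Write the time-course matrix with composite ``line|drug|time|rep`` ids."""
    flat = tc.values.copy()
    flat.columns = [
        _TC_SEP.join([c[0], c[1], f"{float(c[2]):g}", str(c[3])])
        for c in tc.values.columns
    ]
    flat.index.name = "feature_id"
    flat.to_csv(matrix_path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.6f")
    pd.DataFrame(
        {"cell_line": list(tc.tnbc), "tnbc": [tc.tnbc[l] for l in tc.tnbc]}
    ).to_csv(lines_path, sep="\t", index=False)


def read_timecourse(matrix_path, lines_path) -> TimeCourseExperiment:
    df = _read_tsv_matrix(matrix_path)
    try:
        tuples = [
            (line, drug, float(t), int(rep))
            for line, drug, t, rep in (c.split(_TC_SEP) for c in df.columns)
        ]
    except ValueError as exc:
        raise FormatError(
            f"{matrix_path}: sample ids must be line{_TC_SEP}drug{_TC_SEP}"
            f"time{_TC_SEP}rep"
        ) from exc
    df.columns = pd.MultiIndex.from_tuples(
        tuples, names=["cell_line", "drug", "time_h", "replicate"]
    )
    lines = pd.read_csv(lines_path, sep="\t", dtype={"cell_line": str})
    tnbc = dict(zip(lines["cell_line"], lines["tnbc"].astype(bool)))
    return TimeCourseExperiment(df, tnbc)


def setup_logging(seed: int | None = None, level=logging.INFO) -> None:
    """Structured log to stderr, tagged with the run seed."""
    tag = f"seed={seed}" if seed is not None else "seed=?"
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter(f"%(asctime)s bcproteodyn[{tag}] %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)
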
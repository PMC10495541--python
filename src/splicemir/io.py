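"""Domain containers and readers/writers for the pipeline's tabular inputs.

Three kinds of input table are supported:

* expression matrices (miRNA, transcript or gene), delimited text with
  features on rows and samples on columns or the transpose;
* target-site prediction tables in the TarPmiR output style
  (miRNA, transcript, site coordinates, binding probability);
* transcript annotation, either a simple 5-column table or a GTF whose
  exon/CDS features are projected into transcript coordinates.

All intervals are handled as 0-based half-open in transcript coordinates;
GTF genomic input is converted at parse time.  Readers validate and reject
malformed input rather than coercing it, naming the offending record.
"""

from __future__ import annotations

import gzip
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: log2(0.001): the value a log2(x + 0.001) transform assigns to x = 0,
#: i.e. the "not expressed" floor of the abundance matrices.
DEFAULT_FLOOR = math.log2(0.001)

#: tolerance above the floor below which a value counts as "absent"
ABSENT_TOL = 1e-9

Kind = Literal["mirna", "transcript", "gene"]


@dataclass
class ExpressionMatrix:
    """A samples x features table of log2-scale abundances.

    ``floor`` marks the log value that represents "not expressed"; values at
    the floor are permitted and are what the presence filter counts.
    """

    kind: Kind
    values: pd.DataFrame  # index = sample ids, columns = feature ids
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if self.kind not in ("mirna", "transcript", "gene"):
            raise ValueError(f"unknown expression kind {self.kind!r}")
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value for feature {cols[j]!r} in sample {idx[i]!r}"
            )

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def absent_mask(self) -> pd.DataFrame:
        """Boolean mask of values at (or numerically below) the floor."""
        return self.values <= self.floor + ABSENT_TOL

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.kind, self.values.loc[list(sample_ids)], self.floor)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.kind, self.values[list(feature_ids)], self.floor)


@dataclass(frozen=True)
class TargetSiteRecord:
    """One predicted miRNA binding site on a transcript.

    Coordinates are 0-based half-open in transcript space; ``probability``
    is the prediction classifier's binding probability.
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    probability: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid site interval [{self.start},{self.end}) for "
                f"({self.mirna_id}, {self.transcript_id})"
            )
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(
                f"binding probability {self.probability} outside [0,1] for "
                f"({self.mirna_id}, {self.transcript_id})"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its gene and CDS interval in transcript coordinates."""

    transcript_id: str
    gene_id: str
    length: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.transcript_id}: nonpositive length {self.length}")
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise ValueError(
                f"{self.transcript_id}: invalid CDS [{self.cds_start},{self.cds_end}) "
                f"for length {self.length}"
            )


@dataclass
class TranscriptCatalog:
    """Mapping of transcript ids to models, with a gene -> transcripts view."""

    transcripts: Dict[str, TranscriptModel] = field(default_factory=dict)

    def add(self, model: TranscriptModel) -> None:
        if model.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript id {model.transcript_id!r}")
        self.transcripts[model.transcript_id] = model

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __len__(self) -> int:
        return len(self.transcripts)

    def genes(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for tid, model in self.transcripts.items():
            out.setdefault(model.gene_id, []).append(tid)
        for tids in out.values():
            tids.sort()
        return out


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_expression_table(
    path: str | Path,
    kind: Kind,
    floor: float = DEFAULT_FLOOR,
    *,
    samples_on_rows: bool = False,
    rescale_rpm: bool = False,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited expression table.

    By default the first column holds feature ids and the header row holds
    sample ids (features x samples); pass ``samples_on_rows=True`` for the
    transpose.  With ``rescale_rpm=True``, values given as log2(rpm + 1) are
    re-expressed on the log2(rpm + 0.001) scale used throughout the
    analysis, i.e. v -> log2(2^v - 1 + 0.001).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=sep, index_col=0)
    for axis, name in ((df.index, "row"), (df.columns, "column")):
        if axis.has_duplicates:
            dup = axis[axis.duplicated()][0]
            raise ValueError(f"duplicate {name} id {dup!r} in {path}")
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric cell at row {row!r}, column {col!r} in {path}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(f"missing value at row {row!r}, column {col!r} in {path}")
    if not samples_on_rows:
        df = df.T
    df = df.astype(float)
    if rescale_rpm:
        df = np.log2(np.exp2(df) - 1.0 + 0.001)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(kind=kind, values=df, floor=floor)


_SITE_COLUMN_ALIASES = {
    "mirna": "mirna",
    "mir": "mirna",
    "mirna_id": "mirna",
    "transcript": "transcript",
    "transcript_id": "transcript",
    "mrna": "transcript",
    "start": "start",
    "site_start": "start",
    "end": "end",
    "site_end": "end",
    "probability": "probability",
    "prob": "probability",
    "binding_probability": "probability",
}


def read_site_predictions(
    path: str | Path,
    prob_floor: float = 0.0,
    *,
    one_based: bool = False,
    sep: str = "\t",
) -> List[TargetSiteRecord]:
    """Read a TarPmiR-style site table; extra columns are ignored.

    Records with probability < ``prob_floor`` are dropped (the published
    site tables already apply a 0.5 floor).  Set ``one_based=True`` when
    coordinates are 1-based inclusive; they are normalised to 0-based
    half-open.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=sep, float_precision="round_trip")
    rename = {c: _SITE_COLUMN_ALIASES[c.strip().lower()] for c in df.columns
              if c.strip().lower() in _SITE_COLUMN_ALIASES}
    df = df.rename(columns=rename)
    required = {"mirna", "transcript", "start", "end", "probability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} lacks columns: {sorted(missing)}")
    records: List[TargetSiteRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        start = int(row.start) - (1 if one_based else 0)
        end = int(row.end)
        prob = float(row.probability)
        if prob < prob_floor:
            n_dropped += 1
            continue
        records.append(
            TargetSiteRecord(
                mirna_id=str(row.mirna),
                transcript_id=str(row.transcript),
                start=start,
                end=end,
                probability=prob,
            )
        )
    if n_dropped:
        logger.info("dropped %d sites below probability floor %.2f", n_dropped, prob_floor)
    return records


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr: str) -> Dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(attr))


def _catalog_from_gtf(path: Path) -> TranscriptCatalog:
    """Project GTF exon/CDS genomic features into transcript coordinates.

    Exons are ordered 5'->3' (ascending genomic start on '+', descending on
    '-'); cumulative exon lengths give each CDS segment's position on the
    transcript, whose union must be one contiguous interval.
    """
    exons: Dict[str, list] = {}
    cds: Dict[str, list] = {}
    strands: Dict[str, str] = {}
    genes: Dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GTF line in {path}: {line.strip()!r}")
            feature, start, end, strand, attrs = parts[2], int(parts[3]), int(parts[4]), parts[6], parts[8]
            if feature not in ("exon", "CDS"):
                continue
            a = _parse_gtf_attributes(attrs)
            tid = a.get("transcript_id")
            if tid is None:
                raise ValueError(f"GTF {feature} line without transcript_id in {path}")
            gid = a.get("gene_id")
            if gid is None:
                raise ValueError(f"transcript {tid!r} referencing no gene in {path}")
            genes[tid] = gid
            strands[tid] = strand
            # GTF is 1-based inclusive; convert to 0-based half-open
            iv = (start - 1, end)
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)

    catalog = TranscriptCatalog()
    n_skipped = 0
    for tid, ex in exons.items():
        reverse = strands.get(tid) == "-"
        ex_sorted = sorted(ex, reverse=reverse)
        length = sum(e - s for s, e in ex_sorted)
        if tid not in cds:
            n_skipped += 1
            continue
        # transcript-coordinate offset of each exon's 5' end
        offsets = {}
        acc = 0
        for s, e in ex_sorted:
            offsets[(s, e)] = acc
            acc += e - s
        positions = []
        for cs, ce in cds[tid]:
            host = next(((s, e) for s, e in ex_sorted if s <= cs and ce <= e), None)
            if host is None:
                raise ValueError(f"CDS segment [{cs},{ce}) of {tid!r} not contained in an exon")
            s, e = host
            if reverse:
                positions.append((offsets[host] + (e - ce), offsets[host] + (e - cs)))
            else:
                positions.append((offsets[host] + (cs - s), offsets[host] + (ce - s)))
        positions.sort()
        for (s1, e1), (s2, e2) in zip(positions, positions[1:]):
            if e1 != s2:
                raise ValueError(f"CDS of {tid!r} is not contiguous in transcript coordinates")
        catalog.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=genes[tid],
                length=length,
                cds_start=positions[0][0],
                cds_end=positions[-1][1],
            )
        )
    if n_skipped:
        logger.info("skipped %d transcripts without CDS", n_skipped)
    return catalog


def read_transcript_annotation(path: str | Path) -> TranscriptCatalog:
    """Read transcript annotation from a 5-column TSV or a GTF file.

    TSV columns: transcript, gene, length, cds_start, cds_end (header
    optional).  GTF input must carry exon and CDS features; transcripts
    without a CDS are skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.removesuffix(".gz")
    if name.endswith((".gtf", ".gff")):
        return _catalog_from_gtf(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 5:
        raise ValueError(f"annotation TSV {path} must have 5 columns, found {df.shape[1]}")
    # tolerate a header row
    first = df.iloc[0]
    try:
        int(first[2])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    catalog = TranscriptCatalog()
    for row in df.itertuples(index=False):
        tid, gid = str(row[0]), str(row[1])
        if not gid or gid.lower() in ("na", "nan", ""):
            raise ValueError(f"transcript {tid!r} referencing no gene")
        catalog.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                length=int(row[2]),
                cds_start=int(row[3]),
                cds_end=int(row[4]),
            )
        )
    return catalog


RESULT_COLUMNS = [
    "mirna", "gene", "setting", "k", "l", "rmse_full", "rmse_reduced",
    "lrt_stat", "df", "p", "p_adj", "adj_r2_full", "adj_r2_reduced", "cohens_f2",
]


def write_results_table(results: Sequence, path: str | Path) -> None:
    """Write per-pair nested-model results as a TSV (see RESULT_COLUMNS).

    Floats carry 12 significant digits so a read-back reproduces the values.
    """
    rows = []
    for r in results:
        rows.append({
            "mirna": r.mirna_id, "gene": r.gene_id, "setting": r.setting,
            "k": r.k, "l": r.l, "rmse_full": r.rmse_full, "rmse_reduced": r.rmse_reduced,
            "lrt_stat": r.lrt_stat, "df": r.df, "p": r.p, "p_adj": r.p_adj,
            "adj_r2_full": r.adj_r2_full, "adj_r2_reduced": r.adj_r2_reduced,
            "cohens_f2": r.cohens_f2,
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
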
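"""Shared in-memory containers and their strict TSV dialect.

All tabular artifacts are UTF-8, tab-delimited text with an optional block of
``#`` comment lines before the header.  CRLF and LF line endings are accepted
and treated identically.  Readers fail loudly with the 1-based line number of
the first offending row; writers produce byte-stable output (fixed float
format, no timestamps) so that re-running a pipeline with the same seed yields
byte-identical files.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgument, ParseError

FLOAT_FMT = "%.10g"


def _format_float(x: float) -> str:
    return FLOAT_FMT % float(x)


# ---------------------------------------------------------------------------
# low-level TSV helpers
# ---------------------------------------------------------------------------

def _read_table(path) -> tuple[pd.DataFrame, list[int]]:
    """Read a TSV with '#' pre-header comments.

    Returns the frame plus, for each data row, its 1-based line number in the
    file (so parse errors can point at the real line).
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        raw = fh.read()
    lines = raw.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.strip() == "" or line.lstrip().startswith("#"):
            continue
        header_idx = i
        break
    if header_idx is None:
        raise ParseError(f"{path}: no header line found")
    body = [lines[header_idx]]
    line_nos: list[int] = []
    for i in range(header_idx + 1, len(lines)):
        if lines[i].strip() == "":
            continue
        body.append(lines[i])
        line_nos.append(i + 1)
    try:
        df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    return df, line_nos


def _to_float(df: pd.DataFrame, cols: Sequence[str], line_nos: Sequence[int],
              path) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {out[col].iloc[row]!r} in column "
                f"{col!r} at line {line_nos[row]}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(
                f"{path}: missing value in column {col!r} at line {line_nos[row]}"
            )
        out[col] = converted.astype(float)
    return out


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples nonnegative expression table with sample metadata.

    ``values`` is indexed by gene id with one column per sample id;
    ``sample_meta`` is indexed by sample id with columns
    ``genotype, replicate, timepoint, zone`` (the last two may be empty
    strings for perturbation designs).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise InvalidArgument(f"duplicate gene_id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise InvalidArgument(f"duplicate sample_id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidArgument("expression values must be finite")
        if (arr < 0).any():
            raise InvalidArgument("expression values must be >= 0")
        if list(self.sample_meta.index) != list(self.values.columns):
            raise InvalidArgument(
                "sample_meta index must match value columns in order")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def write_tsv(self, expr_path, samples_path) -> None:
        with open(expr_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_id\t" + "\t".join(self.sample_ids) + "\n")
            for gene, row in zip(self.gene_ids, self.values.to_numpy(float)):
                fh.write(gene + "\t" + "\t".join(_format_float(v) for v in row)
                         + "\n")
        meta = self.sample_meta.copy()
        with open(samples_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("sample_id\tgenotype\treplicate\ttimepoint\tzone\n")
            for sid, m in meta.iterrows():
                fh.write("\t".join([
                    str(sid),
                    str(m.get("genotype", "")),
                    str(m.get("replicate", "")),
                    str(m.get("timepoint", "")),
                    str(m.get("zone", "")),
                ]) + "\n")

    @classmethod
    def read_tsv(cls, expr_path, samples_path=None) -> "ExpressionMatrix":
        df, line_nos = _read_table(expr_path)
        _require_columns(df, ["gene_id"], expr_path)
        dup_mask = df["gene_id"].duplicated()
        if dup_mask.any():
            row = int(np.flatnonzero(dup_mask.to_numpy())[0])
            raise ParseError(
                f"{expr_path}: duplicate gene_id {df['gene_id'].iloc[row]!r} "
                f"at line {line_nos[row]}")
        sample_cols = [c for c in df.columns if c != "gene_id"]
        if not sample_cols:
            raise ParseError(f"{expr_path}: no sample columns")
        df = _to_float(df, sample_cols, line_nos, expr_path)
        values = df.set_index("gene_id")[sample_cols]
        if samples_path is not None:
            meta_df, meta_lines = _read_table(samples_path)
            _require_columns(meta_df, ["sample_id", "genotype"], samples_path)
            if meta_df["sample_id"].duplicated().any():
                raise ParseError(f"{samples_path}: duplicate sample_id")
            meta = meta_df.set_index("sample_id")
            missing = [s for s in sample_cols if s not in meta.index]
            if missing:
                raise ParseError(
                    f"{samples_path}: no metadata for sample(s) {missing}")
            meta = meta.loc[sample_cols]
        else:
            meta = pd.DataFrame(
                {"genotype": "", "replicate": "", "timepoint": "", "zone": ""},
                index=pd.Index(sample_cols, name="sample_id"))
        for col in ("replicate", "timepoint", "zone"):
            if col not in meta.columns:
                meta[col] = ""
        meta = meta.fillna("")
        return cls(values=values, sample_meta=meta)


# ---------------------------------------------------------------------------
# ground-truth network / binding set / edges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueEdge:
    regulator: str
    target: str
    effect_size: float

    @property
    def sign(self) -> int:
        return 1 if self.effect_size > 0 else (-1 if self.effect_size < 0 else 0)


@dataclass
class GroundTruthNetwork:
    """Signed ground-truth network over regulators + targets.

    The edge list is ordered deterministically (generation order); ``seed``
    records the entropy the generator used so a network is reproducible
    bit-for-bit.
    """

    regulators: list[str]
    targets: list[str]
    edges: list[TrueEdge]
    seed: int | None = None

    def __post_init__(self) -> None:
        nodes = self.regulators + self.targets
        if len(set(nodes)) != len(nodes):
            raise InvalidArgument("duplicate gene ids in network nodes")
        regset = set(self.regulators)
        nodeset = set(nodes)
        for e in self.edges:
            if e.regulator not in regset:
                raise InvalidArgument(
                    f"edge regulator {e.regulator!r} not in regulator set")
            if e.target not in nodeset:
                raise InvalidArgument(f"edge target {e.target!r} unknown")

    @property
    def nodes(self) -> list[str]:
        return self.regulators + self.targets

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.regulator, e.target) for e in self.edges}

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("regulator\ttarget\teffect_size\tsign\n")
            for e in self.edges:
                fh.write(f"{e.regulator}\t{e.target}\t"
                         f"{_format_float(e.effect_size)}\t{e.sign}\n")

    @classmethod
    def read_tsv(cls, path, regulators: Sequence[str],
                 targets: Sequence[str]) -> "GroundTruthNetwork":
        df, line_nos = _read_table(path)
        _require_columns(df, ["regulator", "target", "effect_size"], path)
        df = _to_float(df, ["effect_size"], line_nos, path)
        edges = [TrueEdge(str(r), str(t), float(w))
                 for r, t, w in zip(df["regulator"], df["target"],
                                    df["effect_size"])]
        return cls(regulators=list(regulators), targets=list(targets),
                   edges=edges)


@dataclass
class BindingSet:
    """Set of (TF, target) pairs, e.g. ChIP-derived direct-binding evidence."""

    pairs: frozenset[tuple[str, str]]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("regulator\ttarget\n")
            for r, t in sorted(self.pairs):
                fh.write(f"{r}\t{t}\n")

    @classmethod
    def read_tsv(cls, path) -> "BindingSet":
        df, line_nos = _read_table(path)
        _require_columns(df, ["regulator", "target"], path)
        pairs = list(zip(df["regulator"].astype(str), df["target"].astype(str)))
        if len(set(pairs)) != len(pairs):
            raise ParseError(f"{path}: duplicate (regulator, target) pair")
        return cls(pairs=frozenset(pairs))


@dataclass(frozen=True)
class WeightedEdge:
    """A candidate regulatory edge scored by forest importance (weight >= 0)."""

    regulator: str
    target: str
    weight: float


@dataclass(frozen=True)
class SignedEdge:
    regulator: str
    target: str
    weight: float
    sign: int          # +1 activation, -1 repression, 0 ambiguous
    votes_pos: int
    votes_neg: int


def write_weighted_edges(edges: Iterable[WeightedEdge], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("regulator\ttarget\tweight\trank\n")
        for rank, e in enumerate(edges, start=1):
            fh.write(f"{e.regulator}\t{e.target}\t"
                     f"{_format_float(e.weight)}\t{rank}\n")


def read_weighted_edges(path) -> list[WeightedEdge]:
    df, line_nos = _read_table(path)
    _require_columns(df, ["regulator", "target", "weight"], path)
    df = _to_float(df, ["weight"], line_nos, path)
    return [WeightedEdge(str(r), str(t), float(w))
            for r, t, w in zip(df["regulator"], df["target"], df["weight"])]


def write_signed_edges(edges: Iterable[SignedEdge], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("regulator\ttarget\tweight\tsign\tvotes_pos\tvotes_neg\n")
        for e in edges:
            fh.write(f"{e.regulator}\t{e.target}\t{_format_float(e.weight)}\t"
                     f"{e.sign}\t{e.votes_pos}\t{e.votes_neg}\n")


def write_sif(edges: Iterable[WeightedEdge], path,
              relation: str = "regulates") -> None:
    """Simple-interaction-format export for network viewers."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for e in edges:
            fh.write(f"{e.regulator}\t{relation}\t{e.target}\n")


# ---------------------------------------------------------------------------
# time course
# ---------------------------------------------------------------------------

@dataclass
class TimeCourse:
    """Ordered time-course series, one genes x timepoints matrix per zone."""

    gene_ids: list[str]
    timepoints: list[str]
    zones: list[str]
    series: dict[str, np.ndarray] = field(repr=False)  # zone -> (G, T)

    def __post_init__(self) -> None:
        if len(self.timepoints) < 3:
            raise InvalidArgument("a time course needs >= 3 timepoints")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidArgument("duplicate gene ids in time course")
        for z in self.zones:
            arr = np.asarray(self.series[z], dtype=float)
            if arr.shape != (len(self.gene_ids), len(self.timepoints)):
                raise InvalidArgument(
                    f"zone {z!r} series shape {arr.shape} does not match "
                    f"({len(self.gene_ids)}, {len(self.timepoints)})")
            if not np.all(np.isfinite(arr)):
                raise InvalidArgument(f"zone {z!r} series contains non-finite values")
            self.series[z] = arr

    def gene_series(self, gene: str, zone: str) -> np.ndarray:
        try:
            idx = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(gene) from None
        return self.series[zone][idx]

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix) -> "TimeCourse":
        """Build a TimeCourse from an expression matrix whose sample metadata
        carries ``timepoint`` and ``zone`` columns."""
        meta = expr.sample_meta
        if (meta["timepoint"].astype(str) == "").any():
            raise InvalidArgument("expression matrix lacks timepoint metadata")
        zones = sorted(set(meta["zone"].astype(str)))
        tps = sorted(set(meta["timepoint"].astype(str)), key=_timepoint_key)
        series = {}
        for z in zones:
            cols = []
            for t in tps:
                match = meta.index[(meta["zone"].astype(str) == z)
                                   & (meta["timepoint"].astype(str) == t)]
                if len(match) != 1:
                    raise InvalidArgument(
                        f"expected exactly one sample for zone={z!r}, "
                        f"timepoint={t!r}; found {len(match)}")
                cols.append(match[0])
            series[z] = expr.values[cols].to_numpy(dtype=float)
        return cls(gene_ids=expr.gene_ids, timepoints=tps, zones=zones,
                   series=series)

    def write_tsv(self, path) -> None:
        cols = [f"{z}:{t}" for z in self.zones for t in self.timepoints]
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_id\t" + "\t".join(cols) + "\n")
            for i, gene in enumerate(self.gene_ids):
                vals = np.concatenate([self.series[z][i] for z in self.zones])
                fh.write(gene + "\t" + "\t".join(_format_float(v) for v in vals)
                         + "\n")

    @classmethod
    def read_tsv(cls, path) -> "TimeCourse":
        df, line_nos = _read_table(path)
        _require_columns(df, ["gene_id"], path)
        if df["gene_id"].duplicated().any():
            row = int(np.flatnonzero(df["gene_id"].duplicated().to_numpy())[0])
            raise ParseError(f"{path}: duplicate gene_id at line {line_nos[row]}")
        data_cols = [c for c in df.columns if c != "gene_id"]
        zones: list[str] = []
        tps: list[str] = []
        for c in data_cols:
            if ":" not in c:
                raise ParseError(
                    f"{path}: time-course column {c!r} is not 'zone:timepoint'")
            z, t = c.split(":", 1)
            if z not in zones:
                zones.append(z)
            if t not in tps:
                tps.append(t)
        df = _to_float(df, data_cols, line_nos, path)
        series = {}
        for z in zones:
            cols = [f"{z}:{t}" for t in tps]
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ParseError(f"{path}: missing column(s) {missing}")
            series[z] = df[cols].to_numpy(dtype=float)
        return cls(gene_ids=[str(g) for g in df["gene_id"]], timepoints=tps,
                   zones=zones, series=series)


def _timepoint_key(t: str):
    try:
        return (0, float(t))
    except ValueError:
        return (1, t)
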
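"""Core types and I/O for 5C contact data.

A 5C experiment measures ligation frequencies between restriction fragments
of a genomic region (here indexed 1..n left to right).  The package stores
one sample as a symmetric ``n x n`` interaction-frequency (IF) matrix with an
explicit measured-mask: cells that were not assayed (missing primers, failed
probes) are flagged, never silently zero.  A labelled collection of such
matrices over one fragment map is a :class:`SamplePanel`; for classification
each matrix is flattened into a feature vector over the measured pairs of a
shared :class:`FeatureIndex`.

File formats: tab-delimited matrices in either a bare numeric dialect
(``plain``) or a my5C-compatible dialect (``my5c``) whose row/column headers
are ``NAME|ASSEMBLY|chrom:start-end`` strings; fragment maps as BED.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ContractError,
    DegenerateDataError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

Dialect = Literal["my5c", "plain"]
MissingPolicy = Literal["intersect", "impute_row_mean"]

#: relative tolerance beyond which two mirror cells count as asymmetric
ASYMMETRY_RTOL = 1e-6

_MY5C_HEADER_RE = re.compile(
    r"^(?P<name>[^|]*)\|(?P<assembly>[^|]*)\|(?P<chrom>[^:|]+):(?P<start>\d+)-(?P<end>\d+)$"
)


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment; coordinates are 1-based inclusive."""

    index: int
    chrom: str
    start: int
    end: int
    primer_orientation: str = "NONE"  # FOR | REV | NONE

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"fragment {self.index}: start {self.start} >= end {self.end}"
            )
        if self.primer_orientation not in ("FOR", "REV", "NONE"):
            raise ValidationError(
                f"fragment {self.index}: bad orientation {self.primer_orientation!r}"
            )


@dataclass(frozen=True)
class FragmentMap:
    """Ordered, non-overlapping restriction fragments numbered 1..n."""

    fragments: tuple[Fragment, ...]

    def __post_init__(self) -> None:
        frags = tuple(self.fragments)
        object.__setattr__(self, "fragments", frags)
        for k, f in enumerate(frags, start=1):
            if f.index != k:
                raise ValidationError(
                    f"fragment indices must be consecutive from 1; got {f.index} at position {k}"
                )
        for a, b in zip(frags, frags[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValidationError(
                    f"fragments {a.index} and {b.index} overlap or are unsorted"
                )

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    @classmethod
    def uniform(
        cls,
        n_fragments: int,
        chrom: str = "chr7",
        start: int = 27_100_000,
        fragment_length: int = 4_000,
    ) -> "FragmentMap":
        """Evenly spaced synthetic map, convenient for simulated panels."""
        frags = []
        pos = start
        for i in range(1, n_fragments + 1):
            frags.append(
                Fragment(
                    index=i,
                    chrom=chrom,
                    start=pos,
                    end=pos + fragment_length - 1,
                    primer_orientation="FOR" if i % 2 else "REV",
                )
            )
            pos += fragment_length
        return cls(tuple(frags))

    def to_bed(self, path: str | Path) -> None:
        """Write as BED (0-based half-open)."""
        with open(path, "w") as fh:
            for f in self.fragments:
                fh.write(
                    f"{f.chrom}\t{f.start - 1}\t{f.end}\tfrag_{f.index}\t0\t"
                    f"{'+' if f.primer_orientation != 'REV' else '-'}\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path) -> "FragmentMap":
        frags = []
        with open(path) as fh:
            for k, line in enumerate(fh, start=1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{path}: BED line {k} has <3 columns")
                chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
                strand = parts[5] if len(parts) > 5 else "+"
                frags.append(
                    Fragment(
                        index=k,
                        chrom=chrom,
                        start=start0 + 1,
                        end=end,
                        primer_orientation="REV" if strand == "-" else "FOR",
                    )
                )
        return cls(tuple(frags))

    def header_labels(self, assembly: str = "hg19") -> list[str]:
        return [
            f"frag_{f.index}|{assembly}|{f.chrom}:{f.start}-{f.end}"
            for f in self.fragments
        ]


@dataclass
class ContactMatrix:
    """Symmetric nonnegative IF matrix with a measured-cell mask.

    ``values[i, j]`` is NaN wherever ``mask[i, j]`` is False; measured cells
    are finite and >= 0.  Indices here are 0-based array positions; fragment
    numbering (1-based) lives in the optional :class:`FragmentMap`.
    """

    values: np.ndarray
    mask: np.ndarray
    fragment_map: FragmentMap | None = None
    #: difference maps (class A minus class B) legitimately carry negatives
    signed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"contact matrix must be square, got {v.shape}")
        m = np.asarray(self.mask, dtype=bool)
        if m.shape != v.shape:
            raise ValidationError("mask shape differs from values shape")
        v = v.copy()
        v[~m] = np.nan
        meas = v[m]
        if np.any(~np.isfinite(meas)):
            raise ValidationError("measured cells must be finite")
        if not self.signed and np.any(meas < 0):
            raise ValidationError("negative interaction frequency")
        if not np.array_equal(m, m.T):
            raise ValidationError("measured mask must be symmetric")
        with np.errstate(invalid="ignore"):
            scale = np.maximum(np.maximum(np.abs(v), np.abs(v.T)), 1.0)
            bad = m & (np.abs(v - v.T) > ASYMMETRY_RTOL * scale)
        if np.any(bad):
            raise ValidationError("measured cells are not symmetric")
        self.values = v
        self.mask = m
        if self.fragment_map is not None and len(self.fragment_map) != v.shape[0]:
            raise ValidationError("fragment map length differs from matrix size")

    @classmethod
    def from_dense(
        cls,
        values: np.ndarray | Sequence[Sequence[float]],
        fragment_map: FragmentMap | None = None,
        signed: bool = False,
    ) -> "ContactMatrix":
        """Build from a dense array; NaN cells become unmeasured."""
        v = np.asarray(values, dtype=float)
        return cls(values=v, mask=np.isfinite(v), fragment_map=fragment_map, signed=signed)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.values.copy(), self.mask.copy(), self.fragment_map, self.signed
        )

    def measured_sum(self, upper_only: bool = True, include_diagonal: bool = True) -> float:
        """Sum of measured cells over the upper triangle."""
        iu = np.triu_indices(self.n, k=0 if include_diagonal else 1)
        vals = self.values[iu]
        return float(np.nansum(vals))

    def __eq__(self, other: object) -> bool:  # value equality, for tests
        if not isinstance(other, ContactMatrix):
            return NotImplemented
        return (
            np.array_equal(self.mask, other.mask)
            and np.allclose(
                np.nan_to_num(self.values), np.nan_to_num(other.values), rtol=0, atol=0
            )
        )


@dataclass(frozen=True)
class PanelSample:
    sample_id: str
    matrix: ContactMatrix
    mll_status: str  # fusion | wt
    subtype: str = "none"  # AF9 | ENL | AF6 | AFX | AF4 | none
    leukemia_type: str = "AML"  # AML | ALL | EC

    def label(self, field_name: str) -> str:
        if field_name not in ("mll_status", "subtype", "leukemia_type"):
            raise ValidationError(f"unknown label field {field_name!r}")
        return getattr(self, field_name)


@dataclass
class SamplePanel:
    """Labelled collection of contact matrices over one fragment map."""

    samples: list[PanelSample]
    fragment_map: FragmentMap | None = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("sample ids must be unique")
        sizes = {s.matrix.n for s in self.samples}
        if len(sizes) > 1:
            raise ValidationError(f"samples have differing matrix sizes: {sizes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def n_fragments(self) -> int:
        return self.samples[0].matrix.n if self.samples else 0

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def labels(self, field_name: str) -> list[str]:
        return [s.label(field_name) for s in self.samples]

    def subset(self, keep: Iterable[str] | None = None, **field_values: str) -> "SamplePanel":
        """Restrict to given sample ids and/or label values, order preserved."""
        keep_set = set(keep) if keep is not None else None
        out = []
        for s in self.samples:
            if keep_set is not None and s.sample_id not in keep_set:
                continue
            if any(s.label(f) != v for f, v in field_values.items()):
                continue
            out.append(s)
        return SamplePanel(out, self.fragment_map)

    def with_labels(self, field_name: str, new_labels: Sequence[str]) -> "SamplePanel":
        """Return a panel with the given label field replaced (e.g. shuffled)."""
        if len(new_labels) != len(self.samples):
            raise ValidationError("label count differs from sample count")
        out = [replace(s, **{field_name: lab}) for s, lab in zip(self.samples, new_labels)]
        return SamplePanel(out, self.fragment_map)


@dataclass(frozen=True)
class FeatureIndex:
    """Ordered contact pairs (1-based fragment indices, i <= j) forming the
    classifier's feature space; ordering is row-major over the upper triangle."""

    pairs: tuple[tuple[int, int], ...]
    n_fragments: int

    def __post_init__(self) -> None:
        seen = set()
        for i, j in self.pairs:
            if not (1 <= i <= j <= self.n_fragments):
                raise ValidationError(f"pair ({i},{j}) outside 1..{self.n_fragments}")
            if (i, j) in seen:
                raise ValidationError(f"duplicate pair ({i},{j})")
            seen.add((i, j))

    def __len__(self) -> int:
        return len(self.pairs)

    def rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based array indices for fancy indexing into matrices."""
        arr = np.asarray(self.pairs, dtype=int)
        return arr[:, 0] - 1, arr[:, 1] - 1


@dataclass(frozen=True)
class FeatureVector:
    sample_id: str
    values: np.ndarray
    index: FeatureIndex

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.index),):
            raise ContractError(
                f"feature vector length {v.shape} != index length {len(self.index)}"
            )
        if np.any(~np.isfinite(v)):
            raise ContractError("feature vector has missing entries")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# matrix I/O


def _parse_cell(tok: str) -> float:
    tok = tok.strip()
    if tok == "" or tok.upper() in ("NA", "NAN", "NULL", "."):
        return np.nan
    try:
        return float(tok)
    except ValueError:
        return np.nan


def read_contact_matrix(path: str | Path, dialect: Dialect = "my5c") -> ContactMatrix:
    """Read a tab-delimited IF matrix.

    ``my5c`` expects a header row and first column of
    ``NAME|ASSEMBLY|chrom:start-end`` strings; ``plain`` is a bare numeric
    table.  Non-numeric or empty cells become unmeasured; a cell unmeasured on
    either side of the diagonal is unmeasured on both.  Measured mirror cells
    differing by more than a relative 1e-6 are averaged with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip() != ""]
    if not rows:
        raise FormatError(f"{path}: empty file")

    fragment_map: FragmentMap | None = None
    if dialect == "my5c":
        header = rows[0]
        # tolerate an empty/label cell in the top-left corner
        col_labels = header[1:]
        body = rows[1:]
        row_labels = [r[0] for r in body]
        cells = [r[1:] for r in body]
        if len(col_labels) != len(row_labels):
            raise FormatError(
                f"{path}: non-square table ({len(row_labels)} rows x {len(col_labels)} cols)"
            )
        fragment_map = _map_from_headers(row_labels)
    elif dialect == "plain":
        cells = rows
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    n = len(cells)
    widths = {len(r) for r in cells}
    if widths != {n}:
        raise FormatError(f"{path}: non-square table (n={n}, row widths {sorted(widths)})")

    values = np.array([[_parse_cell(tok) for tok in row] for row in cells], dtype=float)
    if np.any(values[np.isfinite(values)] < 0):
        raise ValidationError(f"{path}: negative interaction frequency")

    # pairwise contacts are single measurements: symmetrize
    mask = np.isfinite(values) & np.isfinite(values).T
    with np.errstate(invalid="ignore"):
        scale = np.maximum(np.maximum(np.abs(values), np.abs(values.T)), 1.0)
        asym = mask & (np.abs(values - values.T) > ASYMMETRY_RTOL * scale)
    if np.any(asym):
        logger.warning(
            "%s: %d asymmetric cell pairs averaged", path, int(np.sum(asym)) // 2
        )
    sym = 0.5 * (values + values.T)
    out = np.where(mask, sym, np.nan)
    return ContactMatrix(values=out, mask=mask, fragment_map=fragment_map)


def _map_from_headers(labels: Sequence[str]) -> FragmentMap | None:
    frags = []
    for k, lab in enumerate(labels, start=1):
        m = _MY5C_HEADER_RE.match(lab.strip())
        if m is None:
            return None  # headers present but not coordinate-bearing: keep opaque
        frags.append(
            Fragment(
                index=k,
                chrom=m.group("chrom"),
                start=int(m.group("start")),
                end=int(m.group("end")),
            )
        )
    try:
        return FragmentMap(tuple(frags))
    except ValidationError:
        return None


def write_contact_matrix(
    m: ContactMatrix, path: str | Path, dialect: Dialect = "my5c"
) -> None:
    """Write a matrix readable by :func:`read_contact_matrix`; unmeasured
    cells are written as ``NA``."""
    path = Path(path)
    if dialect not in ("my5c", "plain"):
        raise ValidationError(f"unknown dialect {dialect!r}")

    def fmt(i: int, j: int) -> str:
        return "NA" if not m.mask[i, j] else repr(float(m.values[i, j]))

    lines = []
    if dialect == "my5c":
        fmap = m.fragment_map or FragmentMap.uniform(m.n)
        labels = fmap.header_labels()
        lines.append("\t".join(["matrix"] + labels))
        for i in range(m.n):
            lines.append("\t".join([labels[i]] + [fmt(i, j) for j in range(m.n)]))
    else:
        for i in range(m.n):
            lines.append("\t".join(fmt(i, j) for j in range(m.n)))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# panel metadata I/O

METADATA_COLUMNS = ["sample_id", "path", "mll_status", "subtype", "leukemia_type"]


def write_panel(
    panel: SamplePanel, out_dir: str | Path, dialect: Dialect = "my5c"
) -> Path:
    """Write every matrix plus a metadata CSV; returns the metadata path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in panel:
        fname = f"{s.sample_id}.tsv"
        write_contact_matrix(s.matrix, out_dir / fname, dialect=dialect)
        rows.append(
            dict(
                sample_id=s.sample_id,
                path=fname,
                mll_status=s.mll_status,
                subtype=s.subtype,
                leukemia_type=s.leukemia_type,
            )
        )
    meta = out_dir / "metadata.csv"
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(meta, index=False)
    if panel.fragment_map is not None:
        panel.fragment_map.to_bed(out_dir / "fragments.bed")
    return meta


def read_panel(metadata_path: str | Path, dialect: Dialect = "my5c") -> SamplePanel:
    """Load a panel from a metadata CSV; matrix paths resolve relative to it."""
    metadata_path = Path(metadata_path)
    df = pd.read_csv(metadata_path, dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{metadata_path}: missing columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        mpath = Path(row["path"])
        if not mpath.is_absolute():
            mpath = metadata_path.parent / mpath
        samples.append(
            PanelSample(
                sample_id=row["sample_id"],
                matrix=read_contact_matrix(mpath, dialect=dialect),
                mll_status=row["mll_status"],
                subtype=row["subtype"],
                leukemia_type=row["leukemia_type"],
            )
        )
    fmap = samples[0].matrix.fragment_map if samples else None
    bed = metadata_path.parent / "fragments.bed"
    if bed.exists():
        fmap = FragmentMap.from_bed(bed)
    return SamplePanel(samples, fmap)


# ---------------------------------------------------------------------------
# vectorization


def build_feature_index(
    panel: SamplePanel,
    missing_policy: MissingPolicy = "intersect",
    include_diagonal: bool = False,
) -> FeatureIndex:
    """Contact pairs usable as features across the panel.

    ``intersect`` keeps pairs measured in every sample; ``impute_row_mean``
    keeps pairs measured in at least half the samples.  Self-ligation cells
    (i == j) are excluded by default.  Ordering is row-major over the upper
    triangle, so two calls on the same panel are identical.
    """
    if len(panel) == 0:
        raise ValidationError("empty panel")
    n = panel.n_fragments
    counts = np.zeros((n, n), dtype=int)
    for s in panel:
        counts += s.matrix.mask
    if missing_policy == "intersect":
        ok = counts == len(panel)
    elif missing_policy == "impute_row_mean":
        ok = counts >= 0.5 * len(panel)
    else:
        raise ValidationError(f"unknown missing policy {missing_policy!r}")
    k = 0 if include_diagonal else 1
    iu = np.triu_indices(n, k=k)
    keep = ok[iu]
    pairs = tuple(
        (int(i) + 1, int(j) + 1) for i, j, m in zip(iu[0], iu[1], keep) if m
    )
    if not pairs:
        raise DegenerateDataError("no contact pair is measured across the panel")
    return FeatureIndex(pairs=pairs, n_fragments=n)


def panel_feature_matrix(
    panel: SamplePanel,
    index: FeatureIndex,
    missing_policy: MissingPolicy = "intersect",
) -> pd.DataFrame:
    """Samples x features DataFrame; rows indexed by sample id, columns by
    ``"i-j"`` pair names.  Under the impute policy, a missing cell receives
    the mean of that feature over the samples where it was measured."""
    ri, ci = index.rows_cols()
    raw = np.array([s.matrix.values[ri, ci] for s in panel], dtype=float)
    if missing_policy == "intersect":
        if np.any(~np.isfinite(raw)):
            raise ContractError(
                "unmeasured cell under intersect policy; rebuild the feature index"
            )
        X = raw
    else:
        col_mean = np.nanmean(raw, axis=0)
        if np.any(~np.isfinite(col_mean)):
            raise DegenerateDataError("feature unmeasured in every sample")
        X = np.where(np.isfinite(raw), raw, col_mean[None, :])
    cols = [f"{i}-{j}" for i, j in index.pairs]
    return pd.DataFrame(X, index=panel.sample_ids(), columns=cols)


def vectorize(
    m: ContactMatrix,
    index: FeatureIndex,
    missing_policy: MissingPolicy = "intersect",
    impute_values: np.ndarray | None = None,
    sample_id: str = "",
) -> FeatureVector:
    """Flatten one matrix onto a feature index.

    Under ``impute_row_mean`` the caller supplies per-feature fallback values
    (typically training-panel feature means) for cells this matrix lacks.
    """
    ri, ci = index.rows_cols()
    vals = m.values[ri, ci].astype(float)
    bad = ~np.isfinite(vals)
    if np.any(bad):
        if missing_policy == "intersect":
            raise ContractError(
                f"{int(bad.sum())} unmeasured cells under intersect policy"
            )
        if impute_values is None:
            raise ContractError("impute policy requires impute_values")
        vals = np.where(bad, np.asarray(impute_values, dtype=float), vals)
    return FeatureVector(sample_id=sample_id, values=vals, index=index)


def devectorize(vec: FeatureVector) -> ContactMatrix:
    """Place feature values back into a symmetric matrix (other cells unmeasured)."""
    n = vec.index.n_fragments
    values = np.full((n, n), np.nan)
    ri, ci = vec.index.rows_cols()
    values[ri, ci] = vec.values
    values[ci, ri] = vec.values
    return ContactMatrix.from_dense(values)
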
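"""Readers, writers and the variant-filtering stage.

File formats handled here:

* variant matrices — TSV, sites as rows, samples as columns, cells coded
  ``0`` (ancestral), ``1`` (derived), ``.`` (missing);
* VCF-style variant records — only the columns the quality filter needs
  (CHROM POS ID REF ALT FILTER and a per-sample allelic depth);
* annotated Newick — branch lengths are mutation counts and each branch
  carries a ``[...]`` comment listing the mutation names assigned to it;
* population frequency tables — TSV with coordinates and counts.

Coordinates are 1-based inclusive in files and converted to 0-based
half-open intervals internally (VCF convention).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .tree import MutationTree, TreeNode

ANCESTRAL, DERIVED, MISSING = 0, 1, -1
_SYMBOLS = {"0": ANCESTRAL, "1": DERIVED, ".": MISSING}
_REV_SYMBOLS = {ANCESTRAL: "0", DERIVED: "1", MISSING: "."}


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


# ----------------------------------------------------------------------
# variant matrix
# ----------------------------------------------------------------------
@dataclass
class VariantMatrix:
    """Binary (ancestral/derived/missing) calls, sites x samples.

    ``calls[i, j]`` is the state of site ``i`` in sample ``j`` using the
    codes ``0``/``1``/``-1``.  ``target_length_bp`` is the number of bases
    interrogated to find these variants; the default is the 1,495,512-bp
    MSY target of the study design this package models.
    """

    site_names: list[str]
    positions: list[int]
    samples: list[str]
    calls: np.ndarray
    target_length_bp: int = 1_495_512

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_sites, n_samples = len(self.site_names), len(self.samples)
        if self.calls.shape != (n_sites, n_samples):
            raise FormatError(
                f"call grid is {self.calls.shape}, expected "
                f"({n_sites}, {n_samples})"
            )
        if len(self.positions) != n_sites:
            raise FormatError("positions and site_names length mismatch")
        dup = _first_duplicate(self.site_names)
        if dup is not None:
            raise FormatError(f"duplicate site name {dup!r}")
        dup = _first_duplicate(self.samples)
        if dup is not None:
            raise FormatError(f"duplicate sample name {dup!r}")
        bad = set(np.unique(self.calls)) - {ANCESTRAL, DERIVED, MISSING}
        if bad:
            raise FormatError(f"non-binary call codes {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return len(self.site_names)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def derived_samples(self, site: str) -> frozenset[str]:
        i = self.site_names.index(site)
        mask = self.calls[i] == DERIVED
        return frozenset(s for s, m in zip(self.samples, mask) if m)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantMatrix):
            return NotImplemented
        return (
            self.site_names == other.site_names
            and self.positions == other.positions
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
            and self.target_length_bp == other.target_length_bp
        )


def _first_duplicate(names: Sequence[str]) -> Optional[str]:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            return n
        seen.add(n)
    return None


def read_variant_matrix(
    path: Union[str, Path], target_length_bp: int = 1_495_512
) -> VariantMatrix:
    """Read a sites-by-samples TSV matrix.

    Header: ``site<TAB>position<TAB><sample1><TAB>...``.  Cells must be
    ``0``, ``1`` or ``.`` (missing); empty cells are treated as missing.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "site" or header[1] != "position":
            raise FormatError(
                f"{path}: header must start with 'site<TAB>position'"
            )
        samples = header[2:]
        dup = _first_duplicate(samples)
        if dup is not None:
            raise FormatError(f"{path}: duplicate sample name {dup!r}")
        site_names: list[str] = []
        positions: list[int] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(samples) + 2:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(samples) + 2} columns, "
                    f"got {len(cells)}"
                )
            site_names.append(cells[0])
            positions.append(int(cells[1]))
            row = []
            for col, cell in enumerate(cells[2:]):
                if cell == "":
                    cell = "."
                try:
                    row.append(_SYMBOLS[cell])
                except KeyError:
                    raise FormatError(
                        f"{path}:{lineno}: non-binary symbol {cell!r} in "
                        f"column {samples[col]!r}"
                    ) from None
            rows.append(row)
    dup = _first_duplicate(site_names)
    if dup is not None:
        raise FormatError(f"{path}: duplicate site name {dup!r}")
    calls = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return VariantMatrix(site_names, positions, samples, calls, target_length_bp)


def write_variant_matrix(matrix: VariantMatrix, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("site\tposition\t" + "\t".join(matrix.samples) + "\n")
        for i, (name, pos) in enumerate(
            zip(matrix.site_names, matrix.positions)
        ):
            row = "\t".join(_REV_SYMBOLS[int(c)] for c in matrix.calls[i])
            fh.write(f"{name}\t{pos}\t{row}\n")


# ----------------------------------------------------------------------
# VCF-like records and the quality filter
# ----------------------------------------------------------------------
@dataclass
class VariantCall:
    """One variant record, with the fields the quality filter uses."""

    site_name: str
    position: int  # 1-based
    state: str = "derived"
    filter_flag: str = "PASS"
    allelic_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"{self.site_name}: position must be >= 1")
        if self.state not in ("ancestral", "derived", "missing"):
            raise FormatError(f"{self.site_name}: bad state {self.state!r}")
        if self.allelic_depth is not None and self.allelic_depth < 0:
            raise FormatError(f"{self.site_name}: negative allelic depth")


@dataclass
class TargetRegionSet:
    """Non-overlapping genomic intervals, stored 0-based half-open."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_1based_inclusive(
        cls, intervals: Iterable[tuple[int, int]]
    ) -> "TargetRegionSet":
        return cls([(s - 1, e) for s, e in intervals])._normalize()

    def _normalize(self) -> "TargetRegionSet":
        ivs = sorted(self.intervals)
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if e <= s:
                raise FormatError(f"empty interval ({s}, {e})")
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
            else:
                merged.append((s, e))
        self.intervals = merged
        return self

    @property
    def total_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, position_1based: int) -> bool:
        p = position_1based - 1
        return any(s <= p < e for s, e in self.intervals)


def filter_variant_calls(
    records: Sequence[VariantCall],
    regions: Optional[TargetRegionSet] = None,
    min_depth: int = 3,
) -> list[VariantCall]:
    """Quality screen for externally called variants.

    Keeps a record only if it (a) falls inside the target regions (when
    given), (b) is not flagged low-quality (``VqLow``), and (c) has allelic
    depth at or above ``min_depth``.  The default ``min_depth=3`` discards
    depth <= 2, the screen applied to the Complete Genomics call sets this
    package was designed around.  Order is preserved; idempotent.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    kept: list[VariantCall] = []
    for rec in records:
        if min_depth > 0 and rec.allelic_depth is None:
            raise FormatError(
                f"{rec.site_name}: allelic depth required when min_depth > 0"
            )
        if regions is not None and not regions.contains(rec.position):
            continue
        if rec.filter_flag == "VqLow":
            continue
        if min_depth > 0 and rec.allelic_depth < min_depth:
            continue
        kept.append(rec)
    return kept


def read_vcf_like(path: Union[str, Path]) -> list[VariantCall]:
    """Minimal reader for VCF-style variant lines.

    Parses CHROM POS ID REF ALT [QUAL] FILTER and, when a FORMAT/sample
    column pair is present, an ``AD`` (allelic depth) field.  Only the
    fields the quality filter consumes are retained.
    """
    path = Path(path)
    records: list[VariantCall] = []
    with path.open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                raise FormatError(f"{path}: record has {len(cols)} columns")
            pos = int(cols[1])
            name = cols[2] if cols[2] != "." else f"{cols[0]}:{pos}"
            flt = cols[6]
            depth: Optional[int] = None
            if len(cols) >= 10:
                fmt = cols[8].split(":")
                vals = cols[9].split(":")
                if "AD" in fmt:
                    ad = vals[fmt.index("AD")]
                    # AD may list ref,alt depths; take the alt (last) one
                    depth = int(ad.split(",")[-1])
            records.append(
                VariantCall(
                    site_name=name,
                    position=pos,
                    filter_flag=flt,
                    allelic_depth=depth,
                )
            )
    return records


# ----------------------------------------------------------------------
# annotated Newick
# ----------------------------------------------------------------------
def _newick_token(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _emit(node: TreeNode, out: _io.StringIO) -> None:
    if node.children:
        out.write("(")
        for i, child in enumerate(node.children):
            if i:
                out.write(",")
            _emit(child, out)
        out.write(")")
    elif node.label is None:
        raise FormatError("cannot serialize a tree with an unlabeled tip")
    if node.label is not None:
        out.write(_newick_token(node.label))
    out.write(f":{len(node.mutations)}")
    out.write("[" + ",".join(sorted(node.mutations)) + "]")


def write_annotated_newick(tree: MutationTree, path: Union[str, Path]) -> None:
    """Serialize with branch lengths = mutation counts and per-branch
    ``[...]`` comments listing the mutation names."""
    buf = _io.StringIO()
    _emit(tree.root, buf)
    buf.write(";\n")
    Path(path).write_text(buf.getvalue())


def read_annotated_newick(path: Union[str, Path]) -> MutationTree:
    """Parse a tree written by :func:`write_annotated_newick`."""
    dtree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
    )

    def convert(dnode: dendropy.Node) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        muts: set[str] = set()
        for comment in dnode.comments:
            if comment:
                muts.update(m for m in comment.split(",") if m)
        node = TreeNode(label=label, mutations=muts)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        length = dnode.edge.length
        if length is not None and int(length) != len(muts):
            raise FormatError(
                f"branch above {label!r}: length {length} does not match "
                f"{len(muts)} annotated mutations"
            )
        return node

    return MutationTree(convert(dtree.seed_node))


# ----------------------------------------------------------------------
# population frequency tables
# ----------------------------------------------------------------------
def read_frequency_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a TSV of population, lat, lon, n and per-haplogroup counts or a
    single frequency column.  Returns a DataFrame with a ``frequency``
    column when ``count`` is given (count / n)."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"frequency table missing columns {sorted(missing)}")
    if "frequency" not in df.columns:
        if {"count", "n"} <= set(df.columns):
            df["frequency"] = df["count"] / df["n"]
        else:
            raise FormatError(
                "frequency table needs 'frequency' or 'count'+'n' columns"
            )
    bad = df[(df.lat.abs() > 90) | (df.lon.abs() > 180)]
    if len(bad):
        raise FormatError(
            f"out-of-range coordinates for {bad.population.tolist()}"
        )
    bad = df[(df.frequency < 0) | (df.frequency > 1)]
    if len(bad):
        raise FormatError(f"frequency outside [0,1] for {bad.population.tolist()}")
    return df
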
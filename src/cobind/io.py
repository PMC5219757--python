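"""Plain-text readers/writers shared across the pipeline (TSV + BED only)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .evaluation import AnnotationTrack, PPISet
from .regions import BindingCall, CoBindingRegion, RegionTFMatrix

__all__ = [
    "read_bed",
    "write_bed",
    "write_regions_bed",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "read_ppi_tsv",
    "read_annotation_bed",
    "write_calls_tsv",
]


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return intervals


def write_bed(path: str | Path, intervals: Sequence[tuple], extra_cols: bool = True) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_regions_bed(path: str | Path, regions: Sequence[CoBindingRegion]) -> None:
    rows = [
        (r.chrom, r.start, r.end, f"{r.chrom}:{r.start}-{r.end}", r.n_sites)
        for r in regions
    ]
    write_bed(path, rows)


def write_matrix_tsv(path: str | Path, frame: pd.DataFrame, index_label: str = "id") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_ppi_tsv(path: str | Path) -> PPISet:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: PPI file needs 2 columns")
            pairs.append((parts[0], parts[1]))
    return PPISet(pairs=pairs)


def read_annotation_bed(path: str | Path, label: str | None = None) -> AnnotationTrack:
    label = label or Path(path).stem
    return AnnotationTrack(label=label, intervals=read_bed(path))


def write_calls_tsv(directory: str | Path, calls: Sequence[BindingCall]) -> list[Path]:
    """Write one TSV per (factor, cell type) in the point-call dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    groups: dict[tuple[str, str | None], list[BindingCall]] = {}
    for c in calls:
        groups.setdefault((c.factor, c.cell_type), []).append(c)
    paths = []
    for (factor, cell_type), group in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")):
        name = f"{factor}.{cell_type}.calls.tsv" if cell_type else f"{factor}.calls.tsv"
        path = directory / name
        with open(path, "w") as fh:
            for c in sorted(group, key=lambda c: (c.chrom, c.summit)):
                motif = "" if c.motif_present is None else str(int(c.motif_present))
                fh.write(f"{c.chrom}\t{c.summit}\t{motif}\n")
        paths.append(path)
    return paths


def matrix_from_frame(frame: pd.DataFrame) -> RegionTFMatrix:
    return RegionTFMatrix(
        counts=frame.to_numpy(),
        region_ids=[str(i) for i in frame.index],
        factors=[str(c) for c in frame.columns],
    )
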
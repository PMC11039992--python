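"""Readers and writers for the pipeline's file formats.

Conventions: BED is 0-based half-open; GTF exons (1-based closed) are
converted to the internal half-open convention at read time.  All TSV
writers emit a header line and every reader accepts its writer's output.
"""

from __future__ import annotations

import os
from typing import Iterable

import dendropy
import pandas as pd

from .binding import BindingDataset, BindingObservation
from .coevolution import PresenceAbsenceMatrix, build_profiles
from .errors import FormatError
from .splicing.annotations import IntronAnnotation
from .splicing.events import ASEvent
from .splicing.models import GeneModel
from .splicing.retention import IRRecord

EVENT_COLUMNS = [
    "gene_id", "event_type", "chrom", "start", "end", "strand",
    "psi_a", "psi_b", "delta_psi", "probability",
]
IR_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "ir_ratio", "depth"]
BINDING_COLUMNS = ["concentration_uM", "fraction_bound", "replicate"]


# -- trees -------------------------------------------------------------

def read_newick(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        raise FormatError(f"failed to parse Newick: {exc}", path=str(path)) from exc


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# -- BED ---------------------------------------------------------------

def read_bed6(path, source: str | None = None) -> list[IntronAnnotation]:
    """Read intervals from BED6; the name column doubles as the intron
    subtype when it is a recognized value."""
    if source is None:
        source = os.path.splitext(os.path.basename(str(path)))[0]
    records: list[IntronAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"expected >= 6 BED columns, got {len(fields)}",
                    path=str(path), line=lineno,
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}",
                    path=str(path), line=lineno,
                ) from None
            if start >= end:
                raise FormatError(
                    f"start >= end ({start} >= {end})", path=str(path), line=lineno
                )
            subtype = name if name in {"GT-AG", "AT-AC", "other"} else None
            try:
                records.append(
                    IntronAnnotation(
                        chrom=chrom, start=start, end=end, strand=strand,
                        subtype=subtype, sources=frozenset({source}),
                    )
                )
            except FormatError as exc:
                raise FormatError(str(exc), path=str(path), line=lineno) from None
    return records


def write_bed6(records: Iterable[IntronAnnotation], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            name = rec.subtype or ",".join(sorted(rec.sources)) or "."
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{name}\t0\t{rec.strand}\n")


def read_bed12(path) -> dict[str, GeneModel]:
    """Read gene models from BED12 (blocks are exons)."""
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"expected 12 BED columns, got {len(fields)}",
                    path=str(path), line=lineno,
                )
            chrom, start_s, _end, name, _score, strand = fields[:6]
            try:
                start = int(start_s)
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                raise FormatError("malformed BED12 blocks", path=str(path), line=lineno) from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(
                    "block count disagrees with sizes/starts", path=str(path), line=lineno
                )
            if name in genes:
                raise FormatError(f"duplicate gene id {name!r}", path=str(path), line=lineno)
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            try:
                genes[name] = GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons)
            except FormatError as exc:
                raise FormatError(str(exc), path=str(path), line=lineno) from None
    if not genes:
        raise FormatError("no gene models found", path=str(path))
    return genes


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )


def read_gtf_exons(path) -> dict[str, GeneModel]:
    """Assemble gene models from GTF exon lines (1-based closed input)."""
    by_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(
                    f"expected 9 GTF columns, got {len(fields)}",
                    path=str(path), line=lineno,
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            gene_id = None
            for attr in attrs.split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise FormatError("exon without gene_id", path=str(path), line=lineno)
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError("non-integer coordinates", path=str(path), line=lineno) from None
            if start > end:
                raise FormatError(f"start > end ({start} > {end})", path=str(path), line=lineno)
            rec = by_gene.setdefault(gene_id, {"chrom": chrom, "strand": strand, "exons": []})
            rec["exons"].append((start - 1, end))  # to 0-based half-open
    if not by_gene:
        raise FormatError("no exon records found", path=str(path))
    return {
        gid: GeneModel(gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
                       exons=tuple(rec["exons"]))
        for gid, rec in by_gene.items()
    }


# -- TSV tables --------------------------------------------------------

def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"failed to parse TSV: {exc}", path=str(path)) from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns {missing}", path=str(path))
    return df


def read_events_tsv(path) -> list[ASEvent]:
    df = _read_tsv(path, EVENT_COLUMNS)
    events = []
    for row in df.itertuples(index=False):
        events.append(
            ASEvent(
                gene_id=str(row.gene_id), event_type=str(row.event_type),
                chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                strand=str(row.strand), psi_a=float(row.psi_a),
                psi_b=float(row.psi_b), probability=float(row.probability),
                delta_psi=float(row.delta_psi),
            )
        )
    return events


def write_events_tsv(events: Iterable[ASEvent], path, extra: dict | None = None) -> None:
    rows = []
    for ev in events:
        row = {c: getattr(ev, c) for c in EVENT_COLUMNS}
        rows.append(row)
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if extra:
        for name, values in extra.items():
            df[name] = values
    df.to_csv(path, sep="\t", index=False)


def read_ir_tsv(path) -> list[IRRecord]:
    df = _read_tsv(path, IR_COLUMNS)
    return [
        IRRecord(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end), strand=str(r.strand),
            gene_id=str(r.gene_id), ir_ratio=float(r.ir_ratio), depth=int(r.depth),
        )
        for r in df.itertuples(index=False)
    ]


def write_ir_tsv(records: Iterable[IRRecord], path) -> None:
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in IR_COLUMNS} for r in records], columns=IR_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False)


def read_binding_tsv(path) -> BindingDataset:
    df = _read_tsv(path, BINDING_COLUMNS)
    obs = [
        BindingObservation(
            concentration=float(r.concentration_uM),
            fraction_bound=float(r.fraction_bound),
            replicate_id=str(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]
    return BindingDataset(observations=obs)


def write_binding_tsv(data: BindingDataset, path) -> None:
    df = pd.DataFrame(
        [
            {
                "concentration_uM": o.concentration,
                "fraction_bound": o.fraction_bound,
                "replicate": o.replicate_id,
            }
            for o in data.observations
        ],
        columns=BINDING_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_membership_tsv(path, transpose: bool = False) -> PresenceAbsenceMatrix:
    """Read an orthology membership matrix (first column = OG id)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"failed to parse TSV: {exc}", path=str(path)) from exc
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate OG ids {dupes}", path=str(path))
    try:
        return build_profiles(df, transpose=transpose)
    except FormatError as exc:
        raise FormatError(str(exc), path=str(path)) from None
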
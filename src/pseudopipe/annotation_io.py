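"""Reading and writing annotation and track files.

Supported dialects:

* GFF3 (1-based closed coordinates, converted to 0-based half-open on read;
  ``gene`` features with ``exon`` children, biotype in the attribute column)
* BED6 / BED12 (already 0-based half-open; BED12 blocks expand to exons)
* feature-track BED with the subtype label in column 4
* UCSC ``chrom.sizes``-style two-column TSV for the genome layout
"""

from __future__ import annotations

import logging
from pathlib import Path

from .genome import (
    AnnotationSet,
    FeatureTrack,
    GeneRecord,
    GenomeLayout,
    KNOWN_BIOTYPES,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed annotation input; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def read_chrom_sizes(path, sex_chromosomes=("chrX", "chrY")) -> GenomeLayout:
    """Read a two-column (name, length) TSV into a :class:`GenomeLayout`."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(path, lineno, "expected 'name<TAB>length'")
            name, length = parts[0], parts[1]
            if name in lengths:
                raise ParseError(path, lineno, f"duplicate chromosome {name!r}")
            try:
                lengths[name] = int(length)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer length {length!r}") from None
    return GenomeLayout(lengths, frozenset(s for s in sex_chromosomes if s in lengths))


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed attribute {item!r}")
        key, value = item.split("=", 1)
        attrs[key] = value
    return attrs


def read_annotation(path, layout: GenomeLayout) -> AnnotationSet:
    """Read a GFF3 or BED12 annotation file into an :class:`AnnotationSet`.

    The dialect is chosen by file suffix (``.gff3``/``.gff`` vs ``.bed``).
    GFF3 coordinates are converted from 1-based closed to the internal
    0-based half-open convention; unknown biotypes are rejected with the
    offending line number.
    """
    path = Path(path)
    if path.suffix in {".gff3", ".gff"}:
        genes = _read_gff3(path)
    elif path.suffix == ".bed":
        genes = _read_bed12(path)
    else:
        raise ValueError(f"cannot infer dialect of {path} (expected .gff3/.gff/.bed)")
    if not genes:
        logger.warning("annotation file %s contained no gene records", path)
    return AnnotationSet(layout, genes)


def _read_gff3(path) -> list[GeneRecord]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(cols)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attr_field = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if start_i < 1 or end_i < start_i:
                raise ParseError(path, lineno, f"bad GFF3 coordinates {start}..{end}")
            try:
                attrs = _parse_gff3_attributes(attr_field)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            # GFF3 1-based closed -> 0-based half-open
            iv = (start_i - 1, end_i)
            if ftype == "gene":
                gene_id = attrs.get("ID")
                if not gene_id:
                    raise ParseError(path, lineno, "gene feature lacks ID attribute")
                biotype = attrs.get("biotype") or attrs.get("gene_biotype")
                if biotype is None:
                    raise ParseError(path, lineno, f"gene {gene_id} lacks biotype")
                if biotype not in KNOWN_BIOTYPES:
                    raise ParseError(path, lineno, f"unknown biotype {biotype!r}")
                genes[gene_id] = {
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": biotype,
                    "parent_gene": attrs.get("parent_gene"),
                    "exons": [],
                }
                order.append(gene_id)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent not in genes:
                    raise ParseError(path, lineno, f"exon with unknown Parent {parent!r}")
                genes[parent]["exons"].append(iv)
    out = []
    for gene_id in order:
        info = genes[gene_id]
        out.append(
            GeneRecord(
                gene_id=gene_id,
                biotype=info["biotype"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=info["exons"],
                parent_gene=info["parent_gene"],
            )
        )
    return out


def _read_bed12(path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(path, lineno, f"expected 12 BED columns, got {len(cols)}")
            chrom, start, end, name, _score, strand = cols[:6]
            block_count = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(path, lineno, "blockCount does not match block lists")
            chrom_start = int(start)
            exons = [(chrom_start + bs, chrom_start + bs + sz) for bs, sz in zip(starts, sizes)]
            if exons and exons[-1][1] != int(end):
                raise ParseError(path, lineno, "last block does not reach chromEnd")
            # biotype and parent ride in the name as id|biotype[|parent]
            parts = name.split("|")
            if len(parts) < 2 or parts[1] not in KNOWN_BIOTYPES:
                raise ParseError(
                    path, lineno, f"BED12 name {name!r} must be id|biotype[|parent]"
                )
            genes.append(
                GeneRecord(
                    gene_id=parts[0],
                    biotype=parts[1],
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    parent_gene=parts[2] if len(parts) > 2 and parts[2] else None,
                )
            )
    return genes


def write_gff3(annotations: AnnotationSet, path) -> None:
    """Write an :class:`AnnotationSet` as GFF3 (inverse of :func:`read_annotation`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotations.genes:
            span_s, span_e = g.span
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            if g.parent_gene:
                attrs += f";parent_gene={g.parent_gene}"
            fh.write(
                f"{g.chrom}\tpseudopipe\tgene\t{span_s + 1}\t{span_e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tpseudopipe\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def write_bed6(intervals, path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED6."""
    with open(path, "w") as fh:
        for rec in intervals:
            chrom, start, end = rec[:3]
            name = rec[3] if len(rec) > 3 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t+\n")


def read_feature_track(path, feature_class: str) -> FeatureTrack:
    """Read a BED file (subtype label in column 4) into a :class:`FeatureTrack`."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(path, lineno, "expected at least 3 BED columns")
            subtype = cols[3] if len(cols) > 3 and cols[3] != "." else ""
            records.append((cols[0], int(cols[1]), int(cols[2]), subtype))
    return FeatureTrack(feature_class, records)


def write_feature_track(track: FeatureTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, subtype in track.records:
            fh.write(f"{chrom}\t{s}\t{e}\t{subtype or '.'}\n")
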
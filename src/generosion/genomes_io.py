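"""Genome + annotation containers and codon-level utilities.

The analyses in this package compare an ancestral ("template") bacterial
genome against derived endosymbiont genomes.  This module holds the shared
containers: an :class:`OrfRecord` is a single annotated protein-coding gene
(strand-corrected, start codon first), a :class:`GenomeAnnotation` bundles a
genome sequence with its ORF inventory.  It also implements the annotation
intactness rule used to call a candidate ORF "putatively functional": its
length must be at least 90% of its closest relative and it must carry no
frameshifting indel.

Coordinates are 1-based inclusive in files (GFF3 convention) and 0-based
half-open internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "OrfRecord",
    "GenomeAnnotation",
    "load_genome",
    "write_genome",
    "translate_frame",
    "annotation_intact",
    "genome_summary",
    "gc_fraction",
    "revcomp",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C among unambiguous (non-N) bases.

    Ambiguous bases are excluded from the denominator so that draft-assembly
    gap runs do not dilute the estimate.
    """
    n_gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    n_at = seq.count("A") + seq.count("T") + seq.count("a") + seq.count("t")
    total = n_gc + n_at
    if total == 0:
        return float("nan")
    return n_gc / total


@dataclass
class OrfRecord:
    """A single annotated ORF.

    ``start``/``end`` are 1-based inclusive positions on ``contig_id``;
    ``sequence`` is the strand-corrected coding sequence (start codon first).
    ``is_mobile`` flags IS-element / prophage features, which are excluded
    from some comparative analyses and summed as "mobile DNA" in genome
    summaries.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    cog_category: str | None = None
    is_mobile: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.gene_id}: coordinate span {self.end - self.start + 1} "
                f"!= sequence length {len(self.sequence)}"
            )
        if len(self.sequence) < 6:
            raise ValueError(f"{self.gene_id}: ORF shorter than 6 bases")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.gene_id}: non-nucleotide characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeAnnotation:
    """A genome (contig sequences) plus its ORF inventory."""

    genome_id: str
    contigs: dict[str, str]
    orfs: list[OrfRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for orf in self.orfs:
            if orf.gene_id in seen:
                raise ValueError(f"duplicate gene_id {orf.gene_id!r}")
            seen.add(orf.gene_id)
            if orf.contig_id not in self.contigs:
                raise ValueError(
                    f"feature {orf.gene_id!r} references unknown contig {orf.contig_id!r}"
                )
            if orf.start < 1 or orf.end > len(self.contigs[orf.contig_id]):
                raise ValueError(
                    f"feature {orf.gene_id!r} out of bounds on contig {orf.contig_id!r} "
                    f"({orf.start}..{orf.end} vs length {len(self.contigs[orf.contig_id])})"
                )

    @property
    def size(self) -> int:
        """Total genome size (sum of contig lengths)."""
        return sum(len(s) for s in self.contigs.values())

    def orf_map(self) -> dict[str, OrfRecord]:
        return {o.gene_id: o for o in self.orfs}

    def intergenic_mask(self) -> dict[str, np.ndarray]:
        """Per-contig boolean array: True at positions not covered by any ORF."""
        masks = {cid: np.ones(len(seq), dtype=bool) for cid, seq in self.contigs.items()}
        for orf in self.orfs:
            masks[orf.contig_id][orf.start - 1 : orf.end] = False
        return masks

    def intergenic_sequence(self) -> str:
        """Concatenated intergenic sequence across all contigs."""
        parts = []
        for cid, mask in sorted(self.intergenic_mask().items()):
            arr = np.frombuffer(self.contigs[cid].encode(), dtype="S1")
            parts.append(b"".join(arr[mask]).decode())
        return "".join(parts)


# ---------------------------------------------------------------------------
# File IO

_TSV_COLUMNS = ["gene_id", "contig", "start", "end", "strand", "cog", "mobile"]


def _orfs_from_tsv(path: Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype={"cog": "string"})
    missing = set(_TSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation TSV missing columns {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        cog = getattr(rec, "cog", None)
        if pd.isna(cog):
            cog = None
        rows.append(
            dict(
                gene_id=str(rec.gene_id),
                contig=str(rec.contig),
                start=int(rec.start),
                end=int(rec.end),
                strand=str(rec.strand),
                cog=cog,
                mobile=bool(getattr(rec, "mobile", False)),
            )
        )
    return rows


_MOBILE_WORDS = ("is_element", "insertion sequence", "prophage", "transposase", "iselement")


def _orfs_from_gff3(path: Path) -> list[dict]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features():
        if feat.featuretype not in {"gene", "CDS"}:
            continue
        attrs = {k.lower(): v for k, v in feat.attributes.items()}
        gene_id = (attrs.get("id") or attrs.get("name") or [feat.id])[0]
        cog = (attrs.get("cog") or [None])[0]
        mobile_attr = (attrs.get("mobile") or ["0"])[0]
        note = " ".join(attrs.get("note", [])).lower()
        mobile = mobile_attr.lower() in {"1", "true", "yes"} or any(
            w in note for w in _MOBILE_WORDS
        )
        rows.append(
            dict(
                gene_id=gene_id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                cog=cog,
                mobile=mobile,
            )
        )
    return rows


def load_genome(
    fasta_path: str | Path,
    annotation_path: str | Path,
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Load a genome FASTA plus its annotation (GFF3 or 6/7-column TSV).

    ORF sequences are extracted strand-corrected (start codon first).
    A feature naming a contig absent from the FASTA, or with out-of-bounds
    coordinates, is a fatal error naming the offending feature.
    """
    fasta_path = Path(fasta_path)
    annotation_path = Path(annotation_path)
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not contigs:
        raise ValueError(f"{fasta_path}: no FASTA records")
    if annotation_path.suffix.lower() in {".gff", ".gff3"}:
        rows = _orfs_from_gff3(annotation_path)
    else:
        rows = _orfs_from_tsv(annotation_path)
    orfs = []
    for r in rows:
        if r["contig"] not in contigs:
            raise ValueError(
                f"feature {r['gene_id']!r} references contig {r['contig']!r} "
                f"not present in {fasta_path.name}"
            )
        contig_seq = contigs[r["contig"]]
        if r["start"] < 1 or r["end"] > len(contig_seq):
            raise ValueError(
                f"feature {r['gene_id']!r} out of bounds on contig {r['contig']!r}"
            )
        sub = contig_seq[r["start"] - 1 : r["end"]]
        if r["strand"] == "-":
            sub = revcomp(sub)
        orfs.append(
            OrfRecord(
                gene_id=r["gene_id"],
                contig_id=r["contig"],
                start=r["start"],
                end=r["end"],
                strand=r["strand"],
                sequence=sub,
                cog_category=r["cog"],
                is_mobile=r["mobile"],
            )
        )
    return GenomeAnnotation(
        genome_id=genome_id or fasta_path.stem, contigs=contigs, orfs=orfs
    )


def write_genome(
    ann: GenomeAnnotation,
    fasta_path: str | Path,
    annotation_path: str | Path,
    annotation_format: str | None = None,
) -> None:
    """Write genome FASTA + annotation (GFF3 or TSV, inferred from suffix)."""
    fasta_path = Path(fasta_path)
    annotation_path = Path(annotation_path)
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in ann.contigs.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    fmt = annotation_format
    if fmt is None:
        fmt = "gff3" if annotation_path.suffix.lower() in {".gff", ".gff3"} else "tsv"
    if fmt == "gff3":
        with open(annotation_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for orf in ann.orfs:
                attrs = [f"ID={orf.gene_id}"]
                if orf.cog_category:
                    attrs.append(f"cog={orf.cog_category}")
                if orf.is_mobile:
                    attrs.append("mobile=1")
                fh.write(
                    f"{orf.contig_id}\tgenerosion\tgene\t{orf.start}\t{orf.end}\t.\t"
                    f"{orf.strand}\t.\t{';'.join(attrs)}\n"
                )
    else:
        rows = [
            dict(
                gene_id=o.gene_id,
                contig=o.contig_id,
                start=o.start,
                end=o.end,
                strand=o.strand,
                cog=o.cog_category,
                mobile=int(o.is_mobile),
            )
            for o in ann.orfs
        ]
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Codon utilities


def translate_frame(seq: str) -> tuple[str, list[int]]:
    """Translate ``seq`` in frame 0 and report internal stop codons.

    Uses the bacterial/archaeal code, translated literally (no forced
    initiator methionine: GTG translates to V, etc. — frame-disruption
    detection does not depend on start-codon handling).  A trailing partial
    codon is ignored.  The terminal stop codon, if present, is dropped from
    the peptide and excluded from the internal-stop list.

    Returns ``(peptide, internal_stop_codon_indices)``.
    """
    seq = seq.upper()
    n_codons = len(seq) // 3
    pep = str(Seq(seq[: 3 * n_codons]).translate(table=11))
    if pep.endswith("*"):
        pep = pep[:-1]
    stops = [i for i, aa in enumerate(pep) if aa == "*"]
    return pep, stops


def annotation_intact(
    candidate_len: int, best_ortholog_len: int, has_frameshift: bool
) -> bool:
    """Annotation-stage intactness rule for a candidate ORF.

    True iff the candidate is at least 90% of the length of its most closely
    related ORF and contains no frameshifting indel.  Integer arithmetic keeps
    the 90% boundary exact.
    """
    if candidate_len <= 0 or best_ortholog_len <= 0:
        raise ValueError("lengths must be positive")
    return (10 * candidate_len >= 9 * best_ortholog_len) and not has_frameshift


def genome_summary(
    ann: GenomeAnnotation, classifications: pd.DataFrame | None = None
) -> dict:
    """Genome-level summary: size, gene counts, mobile DNA, G+C percent.

    ``classifications`` (optional) is a per-gene table with a ``status``
    column (intact / pseudogene / absent) from the ortholog comparison; when
    given, intact/pseudogene counts come from it, otherwise the raw ORF count
    is reported.  Mobile DNA is the summed length of features flagged
    IS/prophage in the annotation (no overlap merging, no de novo discovery).
    """
    all_seq = "".join(ann.contigs.values())
    out = {
        "genome_id": ann.genome_id,
        "chromosome_size": ann.size,
        "n_orfs": len(ann.orfs),
        "mobile_dna_bases": sum(o.length for o in ann.orfs if o.is_mobile),
        "gc_percent": 100.0 * gc_fraction(all_seq),
    }
    if classifications is not None:
        counts = classifications["status"].value_counts()
        out["n_intact"] = int(counts.get("intact", 0))
        out["n_pseudogenes"] = int(counts.get("pseudogene", 0))
        out["n_absent"] = int(counts.get("absent", 0))
    return out
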
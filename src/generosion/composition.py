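"""Base-composition and divergence metrics.

GC2 is the G+C percentage at second codon positions (strongly constrained by
the encoded protein), GC4 at fourfold-degenerate third positions (a
near-neutral proxy), GCI over intergenic sites.  Divergence (dGC2, dGC4) is
the uncorrected p-distance at those site classes between aligned ortholog
pairs, computed separately for intact genes and pseudogenes; comparing
dGC2 of pseudogenes (dGC2_psi) with intact genes measures the relaxation of
protein-level selection.  Also implements sliding-window G+C skew
((G−C)/(G+C), replichore polarity) and a molecular-clock divergence time.

Degeneracy is assigned from the ancestral codon only: the ancestral genome
is the reference template both symbionts are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .genomes_io import GenomeAnnotation, gc_fraction
from .ortholog_compare import PairwiseAlignment
from .synthetic_data import FOURFOLD_PREFIXES

__all__ = [
    "SiteClasses",
    "classify_sites",
    "gc_percent",
    "composition_summary",
    "site_divergence",
    "gc_skew",
    "divergence_time",
]


@dataclass
class SiteClasses:
    """Site-class index sets: per-gene GC2/GC4 positions (0-based, in gene
    coordinates) and per-contig intergenic positions."""

    gc2: dict[str, np.ndarray] = field(default_factory=dict)
    gc4: dict[str, np.ndarray] = field(default_factory=dict)
    intergenic: dict[str, np.ndarray] = field(default_factory=dict)


def classify_sites(ann: GenomeAnnotation) -> SiteClasses:
    """Classify every position: second codon positions (GC2), fourfold-
    degenerate third positions (GC4), and intergenic positions (GCI).

    GC4 covers the third position of the eight fourfold codon families
    (CTN, GTN, TCN, CCN, ACN, GCN, CGN, GGN); two-fold/three-fold families
    and stop codons never contribute.  Genes whose length is not a multiple
    of three are skipped with a warning.
    """
    sc = SiteClasses()
    for orf in ann.orfs:
        seq = orf.sequence
        if len(seq) % 3 != 0:
            warnings.warn(f"{orf.gene_id}: length not divisible by 3; skipped")
            continue
        n_codons = len(seq) // 3
        starts = 3 * np.arange(n_codons)
        sc.gc2[orf.gene_id] = starts + 1
        prefixes = np.array([seq[p : p + 2] for p in starts])
        sc.gc4[orf.gene_id] = starts[np.isin(prefixes, list(FOURFOLD_PREFIXES))] + 2
    for cid, mask in ann.intergenic_mask().items():
        sc.intergenic[cid] = np.flatnonzero(mask)
    return sc


def gc_percent(sequence: str, positions: np.ndarray | None = None) -> float:
    """G+C percentage over a site set (whole sequence when ``positions`` is
    None).  N sites are excluded from the denominator; an empty class is NaN."""
    if positions is None:
        return 100.0 * gc_fraction(sequence)
    if len(positions) == 0:
        return float("nan")
    arr = np.frombuffer(sequence.encode(), dtype="S1")[positions]
    return 100.0 * gc_fraction(b"".join(arr).decode())


def composition_summary(ann: GenomeAnnotation, sites: SiteClasses | None = None) -> dict:
    """Genome-wide GC2 / GC4 / GCI percentages (pooled over genes)."""
    sites = sites or classify_sites(ann)
    omap = ann.orf_map()
    pools = {"GC2": [], "GC4": []}
    for cls, per_gene in (("GC2", sites.gc2), ("GC4", sites.gc4)):
        for gid, pos in per_gene.items():
            if len(pos):
                seq = omap[gid].sequence
                arr = np.frombuffer(seq.encode(), dtype="S1")[pos]
                pools[cls].append(arr)
    out = {"genome_id": ann.genome_id}
    for cls, chunks in pools.items():
        seq = b"".join(np.concatenate(chunks)) .decode() if chunks else ""
        out[cls] = 100.0 * gc_fraction(seq) if seq else float("nan")
    out["GCI"] = 100.0 * gc_fraction(ann.intergenic_sequence())
    return out


def site_divergence(
    alignments: dict[str, PairwiseAlignment],
    sites: SiteClasses,
    site_class: str,
    statuses: pd.Series | dict[str, str] | None = None,
    status_filter: str | tuple[str, ...] = ("intact", "pseudogene"),
) -> float:
    """Pooled p-distance (mismatches / comparable sites) at a site class.

    Class sites are projected through gap-free alignment columns only, so
    frameshifted regions do not contaminate the comparison.  ``site_class``
    is ``"gc2"`` or ``"gc4"``; ``statuses`` (gene_id -> status) with
    ``status_filter`` restricts to intact genes or pseudogenes.  NaN when no
    site is comparable.
    """
    if site_class not in ("gc2", "gc4"):
        raise ValueError("site_class must be 'gc2' or 'gc4'")
    if isinstance(status_filter, str):
        status_filter = (status_filter,)
    per_gene = sites.gc2 if site_class == "gc2" else sites.gc4
    if statuses is not None and not isinstance(statuses, dict):
        statuses = statuses.to_dict()
    n_sites = 0
    n_mismatch = 0
    for gid, aln in alignments.items():
        if statuses is not None and statuses.get(gid) not in status_filter:
            continue
        pos = per_gene.get(gid)
        if pos is None or len(pos) == 0:
            continue
        ref2qry = aln.ref_to_qry_base()
        ref = aln.aligned_ref.replace("-", "")
        full_ref_start = aln.ref_start
        for p in pos:
            q = ref2qry.get(int(p))
            if q is None:
                continue
            rb = ref[int(p) - full_ref_start]
            n_sites += 1
            if rb != q:
                n_mismatch += 1
    if n_sites == 0:
        return float("nan")
    return n_mismatch / n_sites


def gc_skew(
    contig: str, window: int = 40_000, step: int | None = None
) -> pd.DataFrame:
    """Sliding-window G+C skew: (G−C)/(G+C) per window.

    Returns a table with the window start (0-based), end, midpoint, and skew;
    default step is half the window.  Windows with no G or C yield NaN.
    """
    if window > len(contig):
        raise ValueError("window exceeds contig length")
    step = step or max(1, window // 2)
    arr = np.frombuffer(contig.upper().encode(), dtype="S1")
    is_g = np.concatenate([[0], np.cumsum(arr == b"G")])
    is_c = np.concatenate([[0], np.cumsum(arr == b"C")])
    starts = np.arange(0, len(contig) - window + 1, step)
    g = is_g[starts + window] - is_g[starts]
    c = is_c[starts + window] - is_c[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(g + c > 0, (g - c) / np.maximum(g + c, 1), np.nan)
    return pd.DataFrame(
        {"start": starts, "end": starts + window, "midpoint": starts + window // 2, "skew": skew}
    )


def divergence_time(
    d4: float, mu_s: float, generations_per_year_scaling: float = 1.0
) -> float:
    """Molecular-clock divergence time in years: t = d4 / (2 μs g).

    ``d4`` is the pairwise divergence at fourfold-degenerate sites, ``mu_s``
    the synonymous substitution rate per site per year on one lineage; the
    factor 2 accounts for both lineages accumulating substitutions since the
    split.  ``generations_per_year_scaling`` rescales clocks calibrated in
    other units; no particular value is claimed correct, default 1.
    """
    if d4 < 0:
        raise ValueError("d4 must be >= 0")
    if mu_s <= 0 or generations_per_year_scaling <= 0:
        raise ValueError("mu_s and scaling must be positive")
    return d4 / (2.0 * mu_s * generations_per_year_scaling)
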
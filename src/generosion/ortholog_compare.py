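"""Ortholog alignment, intact/pseudogene/absent classification, and
mutation-event extraction.

Each ancestral ORF is aligned against its derived locus with a local
affine-gap aligner (match +1, mismatch −2, gap of length L costs 5 + L).
A candidate is *intact* when the alignment spans >99% of the ancestral ORF
(>90% for ORFs under 300 nt) with no frameshifting indel and no premature
stop codon in the ancestral reading frame; *absent* when no locus aligns
above a low coverage floor (large deletion); otherwise a *pseudogene*.

Disrupting mutations are categorized as internal insertions / deletions,
5'/3' terminal deletions, nonsense substitutions, and IS-element insertions.
Nonsense calls project substitutions onto the ancestral codon frame using
only codons whose three reference positions align gap-free, so the call is
independent of any frameshift introduced by an indel elsewhere in the gene.

Because an optimal local alignment under the above scoring refuses to bridge
a kilobase-scale IS-element insertion, catalog IS matches are excised from
the derived locus *before* alignment (mirroring in-silico removal of mobile
elements prior to whole-genome alignment) and logged as is_element events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import stats
from Bio import Align

from .genomes_io import GenomeAnnotation, STOP_CODONS, revcomp
from .synthetic_data import CATEGORIES

__all__ = [
    "Scoring",
    "PairwiseAlignment",
    "OrthologClass",
    "MutationEvent",
    "align_orf",
    "classify_ortholog",
    "extract_mutations",
    "excise_is_elements",
    "compare_genomes",
    "spectrum",
    "mutation_density",
    "poisson_dispersion",
]


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring: gap of length L costs ``gap_open + gap_extend*L``."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def aligner(self, match_bonus: float = 0.0) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner(
            mode="local", match_score=self.match + match_bonus,
            mismatch_score=self.mismatch,
        )
        # biopython's open_gap_score includes the first gapped position
        a.open_gap_score = self.gap_open + self.gap_extend
        a.extend_gap_score = self.gap_extend
        return a

    def gap_cost(self, length: int) -> float:
        return -(self.gap_open + self.gap_extend * length)


@dataclass
class PairwiseAlignment:
    """A gapped local alignment of an ancestral ORF against a derived locus.

    ``indels``: (ref_position, length, kind) with kind 'ins' (extra derived
    sequence) or 'del' (missing ancestral sequence); ``substitutions``:
    (ref_position, ref_base, qry_base).  ``ref_coverage`` is the fraction of
    the ancestral ORF spanned by the alignment.
    """

    gene_id: str
    ref_len: int
    qry_len: int
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    aligned_ref: str
    aligned_qry: str
    score: float
    indels: list[tuple[int, int, str]] = field(default_factory=list)
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    insert_seqs: dict[int, str] = field(default_factory=dict)

    @property
    def ref_coverage(self) -> float:
        return (self.ref_end - self.ref_start) / self.ref_len

    def ref_to_qry_base(self) -> dict[int, str]:
        """Map of gap-free aligned ref positions to the derived base."""
        out = {}
        rp, qp = self.ref_start, self.qry_start
        for r, q in zip(self.aligned_ref, self.aligned_qry):
            if r != "-" and q != "-":
                out[rp] = q
            if r != "-":
                rp += 1
            if q != "-":
                qp += 1
        return out


def align_orf(ref_seq: str, qry_seq: str, scoring: Scoring = Scoring(), gene_id: str = "") -> PairwiseAlignment:
    """Optimal local alignment of an ancestral ORF against a derived locus.

    Identical sequences short-circuit to the trivial self-alignment.  Score
    ties are broken toward the alignment with the most matched positions (an
    infinitesimal match bonus during the DP; the reported score is the exact
    score of the chosen path under the nominal scoring).  Among full-score
    co-optimal paths this prefers gapped alignments that span a disrupted
    terminus over silently trimming it, so frameshifts near gene ends stay
    visible.
    """
    if not ref_seq or not qry_seq:
        raise ValueError("sequences must be nonempty")
    ref_seq, qry_seq = ref_seq.upper(), qry_seq.upper()
    if ref_seq == qry_seq:
        n = len(ref_seq)
        return PairwiseAlignment(
            gene_id=gene_id, ref_len=n, qry_len=n, ref_start=0, ref_end=n,
            qry_start=0, qry_end=n, aligned_ref=ref_seq, aligned_qry=qry_seq,
            score=scoring.match * n,
        )
    # nominal parameters are integral, so a 1e-6 match bonus can never turn a
    # nominally suboptimal path optimal at these sequence lengths
    aligner = scoring.aligner(match_bonus=1e-6)
    aln = aligner.align(ref_seq, qry_seq)[0]
    ref_blocks, qry_blocks = aln.aligned
    if len(ref_blocks) == 0:  # no scoring-positive local similarity at all
        return PairwiseAlignment(
            gene_id=gene_id, ref_len=len(ref_seq), qry_len=len(qry_seq),
            ref_start=0, ref_end=0, qry_start=0, qry_end=0,
            aligned_ref="", aligned_qry="", score=0.0,
        )
    indels: list[tuple[int, int, str]] = []
    subs: list[tuple[int, str, str]] = []
    insert_seqs: dict[int, str] = {}
    a_ref: list[str] = []
    a_qry: list[str] = []
    for k, ((rs, re), (qs, qe)) in enumerate(zip(ref_blocks, qry_blocks)):
        if k > 0:
            prev_re = ref_blocks[k - 1][1]
            prev_qe = qry_blocks[k - 1][1]
            if rs > prev_re:  # gap in query = deletion of ancestral sequence
                indels.append((int(prev_re), int(rs - prev_re), "del"))
                a_ref.append(ref_seq[prev_re:rs])
                a_qry.append("-" * (rs - prev_re))
            if qs > prev_qe:  # gap in ref = inserted derived sequence
                indels.append((int(prev_re), int(qs - prev_qe), "ins"))
                insert_seqs[int(prev_re)] = qry_seq[prev_qe:qs]
                a_ref.append("-" * (qs - prev_qe))
                a_qry.append(qry_seq[prev_qe:qs])
        a_ref.append(ref_seq[rs:re])
        a_qry.append(qry_seq[qs:qe])
        for off in range(re - rs):
            rb, qb = ref_seq[rs + off], qry_seq[qs + off]
            if rb != qb:
                subs.append((rs + off, rb, qb))
    n_aligned = int(sum(re - rs for rs, re in ref_blocks))
    score = (
        scoring.match * (n_aligned - len(subs))
        + scoring.mismatch * len(subs)
        - sum(scoring.gap_cost(size) for _, size, _ in indels)
    )
    return PairwiseAlignment(
        gene_id=gene_id,
        ref_len=len(ref_seq),
        qry_len=len(qry_seq),
        ref_start=int(ref_blocks[0][0]),
        ref_end=int(ref_blocks[-1][1]),
        qry_start=int(qry_blocks[0][0]),
        qry_end=int(qry_blocks[-1][1]),
        aligned_ref="".join(a_ref),
        aligned_qry="".join(a_qry),
        score=float(score),
        indels=indels,
        substitutions=subs,
        insert_seqs=insert_seqs,
    )


@dataclass
class MutationEvent:
    """One disrupting change, categorized per the allelic-spectrum columns."""

    gene_id: str
    category: str
    ref_position: int
    size: int  # bases; 0 for nonsense

    @property
    def frameshifting(self) -> bool:
        return self.category in ("internal_insertion", "internal_deletion") and self.size % 3 != 0


@dataclass
class OrthologClass:
    gene_id: str
    status: str  # intact | pseudogene | absent
    coverage: float
    reasons: list[str] = field(default_factory=list)


def _matches_catalog(insert: str, is_catalog: list[str]) -> bool:
    """True when ``insert`` matches a catalog IS at >=80% identity over
    >=80% of the catalog sequence length."""
    for is_seq in is_catalog:
        if len(insert) < 0.8 * len(is_seq):
            continue
        k = int(0.2 * len(is_seq)) + 1
        res = edlib.align(is_seq, insert, mode="HW", task="distance", k=k)
        if res["editDistance"] != -1 and res["editDistance"] <= 0.2 * len(is_seq):
            return True
    return False


def nonsense_codons(aln: PairwiseAlignment) -> list[int]:
    """Codon indices where the derived sequence carries a premature stop in
    the ancestral frame that the ancestral codon itself does not, using only
    codons aligned gap-free (so the call is unaffected by frameshifts
    elsewhere in the gene)."""
    ref2qry = aln.ref_to_qry_base()
    ref = aln.aligned_ref.replace("-", "")
    out = []
    n_codons = aln.ref_len // 3
    for ci in range(0, n_codons - 1):  # exclude the terminal stop codon
        p = 3 * ci
        if p in ref2qry and p + 1 in ref2qry and p + 2 in ref2qry:
            qcod = ref2qry[p] + ref2qry[p + 1] + ref2qry[p + 2]
            rcod = ref[p - aln.ref_start : p + 3 - aln.ref_start]
            if qcod in STOP_CODONS and rcod not in STOP_CODONS:
                out.append(ci)
    return out


def extract_mutations(
    aln: PairwiseAlignment,
    is_catalog: list[str] | None = None,
    terminal_min: int = 1,
    pre_excised_is: list["MutationEvent"] | None = None,
) -> list[MutationEvent]:
    """Categorize the disrupting mutations visible in an alignment.

    Unaligned ancestral termini of at least ``terminal_min`` bases count as
    5'/3' terminal deletions; deletions touching the first/last ancestral
    codon are terminal as well.  Insertions matching the IS catalog are
    is_element events, other insertions internal.  Nonsense events come from
    the gap-free codon projection.  ``pre_excised_is`` carries IS events
    already removed before alignment.
    """
    is_catalog = is_catalog or []
    events: list[MutationEvent] = list(pre_excised_is or [])
    gid = aln.gene_id
    if aln.ref_start >= terminal_min:
        events.append(MutationEvent(gid, "five_prime_deletion", 0, aln.ref_start))
    tail = aln.ref_len - aln.ref_end
    if tail >= terminal_min:
        events.append(MutationEvent(gid, "three_prime_deletion", aln.ref_end, tail))
    for pos, size, kind in aln.indels:
        if kind == "del":
            if pos < 3:
                cat = "five_prime_deletion"
            elif pos + size > aln.ref_len - 3:
                cat = "three_prime_deletion"
            else:
                cat = "internal_deletion"
            events.append(MutationEvent(gid, cat, pos, size))
        else:
            insert = aln.insert_seqs.get(pos, "")
            if is_catalog and _matches_catalog(insert, is_catalog):
                events.append(MutationEvent(gid, "is_element", pos, size))
            else:
                events.append(MutationEvent(gid, "internal_insertion", pos, size))
    for ci in nonsense_codons(aln):
        events.append(MutationEvent(gid, "nonsense", 3 * ci, 0))
    return events


def classify_ortholog(
    aln: PairwiseAlignment | None,
    ref_len: int,
    found: bool = True,
    events: list[MutationEvent] | None = None,
    absent_threshold: float = 0.20,
) -> OrthologClass:
    """Apply the intact / pseudogene / absent rule to one ortholog pair.

    Intact requires coverage >0.99 (>0.90 for ORFs <300 nt), no frameshifting
    indel, no premature stop, and no IS insertion.  Below
    ``absent_threshold`` coverage (or no locus at all) the gene is absent —
    lost via large deletion.
    """
    gid = aln.gene_id if aln is not None else ""
    if not found or aln is None:
        return OrthologClass(gid, "absent", 0.0, ["no_locus"])
    cov = aln.ref_coverage
    if cov < absent_threshold:
        return OrthologClass(aln.gene_id, "absent", cov, ["coverage_below_absent_threshold"])
    if events is None:
        events = extract_mutations(aln)
    reasons = []
    cov_needed = 0.99 if ref_len >= 300 else 0.90
    if cov <= cov_needed:
        reasons.append("low_coverage")
    if any(e.frameshifting for e in events):
        reasons.append("frameshift_indel")
    if any(e.category == "nonsense" for e in events):
        reasons.append("premature_stop")
    if any(e.category == "is_element" for e in events):
        reasons.append("is_insertion")
    if any(e.category in ("five_prime_deletion", "three_prime_deletion") for e in events):
        reasons.append("truncation")
    # an in-frame internal indel alone does not disqualify intactness,
    # matching the span/frameshift/stop wording of the rule
    disqualifying = {"low_coverage", "frameshift_indel", "premature_stop", "is_insertion"}
    if disqualifying & set(reasons):
        return OrthologClass(aln.gene_id, "pseudogene", cov, reasons)
    return OrthologClass(aln.gene_id, "intact", cov, reasons)


def excise_is_elements(
    qry_seq: str, is_catalog: list[str], max_rounds: int = 50
) -> tuple[str, list[tuple[int, int]]]:
    """Remove catalog IS-element copies from a derived locus before alignment.

    Returns the cleaned sequence and a list of (position_in_cleaned_seq,
    excised_length).  Matching uses infix edit distance <= 20% of the IS
    length, so diverged copies are still recognized.
    """
    excisions: list[tuple[int, int]] = []
    seq = qry_seq
    for _ in range(max_rounds):
        best = None
        for is_seq in is_catalog:
            k = int(0.2 * len(is_seq))
            res = edlib.align(is_seq, seq, mode="HW", task="locations", k=k)
            if res["editDistance"] != -1 and res["locations"]:
                s, e = res["locations"][0]
                if best is None or res["editDistance"] < best[0]:
                    best = (res["editDistance"], s, e)
        if best is None:
            break
        _, s, e = best
        excisions.append((s, e - s + 1))
        seq = seq[:s] + seq[e + 1 :]
    return seq, excisions


@dataclass
class ComparisonResult:
    """Per-gene classifications, extracted events, and retained alignments."""

    classifications: pd.DataFrame
    events: pd.DataFrame
    alignments: dict[str, PairwiseAlignment]

    def status_map(self) -> pd.Series:
        return self.classifications.set_index("gene_id")["status"]


def compare_genomes(
    ancestral: GenomeAnnotation,
    derived: GenomeAnnotation,
    is_catalog: list[str] | None = None,
    scoring: Scoring = Scoring(),
    absent_threshold: float = 0.20,
    terminal_min: int = 1,
    keep_alignments: bool = True,
) -> ComparisonResult:
    """Classify every ancestral ORF against the derived genome.

    Pairing is by shared gene_id (exact for synthetic truth-labeled data);
    an id missing from the derived annotation is absent.  When an IS catalog
    is supplied, catalog copies are excised from each derived locus before
    alignment and logged as is_element events.
    """
    is_catalog = is_catalog or []
    derived_map = derived.orf_map()
    class_rows = []
    event_rows = []
    alignments: dict[str, PairwiseAlignment] = {}
    for orf in ancestral.orfs:
        gid = orf.gene_id
        dorf = derived_map.get(gid)
        if dorf is None:
            class_rows.append(
                dict(gene_id=gid, status="absent", coverage=0.0, reasons="no_locus")
            )
            continue
        qry = dorf.sequence
        pre_is: list[MutationEvent] = []
        if is_catalog:
            qry, excised = excise_is_elements(qry, is_catalog)
            for pos, size in excised:
                pre_is.append(MutationEvent(gid, "is_element", pos, size))
        aln = align_orf(orf.sequence, qry, scoring, gene_id=gid)
        events = extract_mutations(
            aln, is_catalog, terminal_min=terminal_min, pre_excised_is=pre_is
        )
        cls = classify_ortholog(
            aln, orf.length, found=True, events=events, absent_threshold=absent_threshold
        )
        if cls.status == "absent":
            events = []
        class_rows.append(
            dict(
                gene_id=gid,
                status=cls.status,
                coverage=round(cls.coverage, 6),
                reasons=",".join(cls.reasons),
            )
        )
        for ev in events:
            event_rows.append(
                dict(
                    gene_id=gid,
                    category=ev.category,
                    ref_position=ev.ref_position,
                    size=ev.size,
                    frameshifting=ev.frameshifting,
                )
            )
        if keep_alignments:
            alignments[gid] = aln
    return ComparisonResult(
        classifications=pd.DataFrame(
            class_rows, columns=["gene_id", "status", "coverage", "reasons"]
        ),
        events=pd.DataFrame(
            event_rows,
            columns=["gene_id", "category", "ref_position", "size", "frameshifting"],
        ),
        alignments=alignments,
    )


def spectrum(
    events: pd.DataFrame, genome_id: str = "", n_pseudogenes: int | None = None
) -> pd.DataFrame:
    """Allelic spectrum: counts and proportions per disrupting-mutation
    category (one row, columns in the canonical category order)."""
    total = len(events)
    row: dict[str, object] = {
        "genome_id": genome_id,
        "n_pseudogenes": n_pseudogenes
        if n_pseudogenes is not None
        else events["gene_id"].nunique() if total else 0,
        "total_disrupting_mutations": total,
    }
    counts = events["category"].value_counts() if total else {}
    for cat in CATEGORIES:
        c = int(counts.get(cat, 0)) if total else 0
        row[f"{cat}_count"] = c
        row[f"{cat}_prop"] = c / total if total else 0.0
        row[f"{cat}_percent"] = round(100.0 * c / total) if total else 0
    return pd.DataFrame([row])


def mutation_density(
    n_events: int, ancestral_len: int, current_len: int | None = None, mode: str = "ancestral"
) -> float:
    """Disrupting mutations per kb of the ancestral ORF (``mode='ancestral'``)
    or of the observed derived locus (``mode='current'``).  NaN when the
    current length is zero/unknown."""
    if mode == "ancestral":
        length = ancestral_len
    elif mode == "current":
        length = current_len if current_len else 0
    else:
        raise ValueError("mode must be 'ancestral' or 'current'")
    if not length:
        return float("nan")
    return n_events / (length / 1000.0)


def mutation_densities(
    classifications: pd.DataFrame,
    events: pd.DataFrame,
    ancestral: GenomeAnnotation,
    derived: GenomeAnnotation,
    mode: str = "ancestral",
) -> pd.Series:
    """Per-pseudogene mutation density (events per kb)."""
    anc_len = {o.gene_id: o.length for o in ancestral.orfs}
    der_len = {o.gene_id: o.length for o in derived.orfs}
    counts = events.groupby("gene_id").size()
    pseudo = classifications.loc[classifications["status"] == "pseudogene", "gene_id"]
    out = {}
    for gid in pseudo:
        out[gid] = mutation_density(
            int(counts.get(gid, 0)), anc_len[gid], der_len.get(gid), mode
        )
    return pd.Series(out, name=f"density_{mode}")


def poisson_dispersion(counts) -> tuple[float, float, float]:
    """Variance-to-mean ratio and a chi-square dispersion test against a
    Poisson with matched mean.

    The statistic (n−1)·s²/x̄ is chi-square with n−1 degrees of freedom under
    the Poisson null; the reported p is the upper tail (overdispersion).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two pseudogene counts")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("all counts are zero; pseudogenes must carry >=1 event")
    var = counts.var(ddof=1)
    vmr = var / mean
    chi2 = (counts.size - 1) * vmr
    p = float(stats.chi2.sf(chi2, counts.size - 1))
    return float(vmr), float(chi2), p
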
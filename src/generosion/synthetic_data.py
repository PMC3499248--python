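"""Truth-labeled synthetic genome-erosion generator.

Emulates the degeneration of a derived endosymbiont genome from a
free-living-like ancestral template: an inventory of ~4,000 codon-structured
ORFs with a right-skewed (gamma) length distribution, of which a designated
"neutral class" evolves without purifying selection.  Neutral genes accumulate
length-proportional disrupting mutations — small frameshifting indels,
nonsense substitutions, terminal truncations, IS-element insertions — and a
configurable fraction is removed wholly (the "absent" class).  All retained
genes additionally accumulate AT-biased background point substitutions,
fastest at fourfold-degenerate third-codon positions.

Every injected change is logged in a :class:`TruthTable`, so downstream
classification, spectrum, composition and Monte Carlo estimation stages can be
validated closed-loop without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomes_io import (
    GenomeAnnotation,
    OrfRecord,
    STOP_CODONS,
    revcomp,
    write_genome,
)

__all__ = [
    "CATEGORIES",
    "SOPE_CATEGORY_MIX",
    "ErosionConfig",
    "TruthTable",
    "generate_ancestral",
    "erode",
    "make_is_element",
]

#: Disrupting-mutation categories, in the column order of the allelic spectrum.
CATEGORIES = (
    "internal_insertion",
    "internal_deletion",
    "five_prime_deletion",
    "three_prime_deletion",
    "nonsense",
    "is_element",
)

#: Category proportions observed for the weevil symbiont (SOPE): the default
#: mix the generator injects.
SOPE_CATEGORY_MIX = {
    "internal_insertion": 0.19,
    "internal_deletion": 0.34,
    "five_prime_deletion": 0.07,
    "three_prime_deletion": 0.11,
    "nonsense": 0.19,
    "is_element": 0.10,
}

_CATEGORY_ALIASES = {"IS_insertion": "is_element", "is_insertion": "is_element"}

#: Frameshifting small-indel lengths: 1–10 bp with length mod 3 != 0.
INDEL_LENGTHS = (1, 2, 4, 5, 7, 8, 10)

STOPS = tuple(sorted(STOP_CODONS))

# Fourfold-degenerate codon families (first two bases); the third position of
# these codons is synonymous for any base.
FOURFOLD_PREFIXES = frozenset({"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"})

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ErosionConfig:
    """Parameters of the ancestral genome and of the erosion process.

    Lengths are in bases; rates are per-site substitution probabilities over
    the whole simulated divergence (i.e. realized pairwise divergence, not a
    per-year rate).  ``at_bias`` is the probability that a substitution at a
    degenerate (or intergenic) site moves toward A/T.  ``category_mix`` is the
    distribution of disrupting-event categories; the default is the observed
    SOPE allelic spectrum.  ``is_catalog=None`` auto-generates one synthetic
    IS element; an explicitly empty catalog combined with a nonzero
    ``is_element`` category weight is an error.
    """

    seed: int
    n_genes: int = 4000
    length_mean: float = 950.0
    length_shape: float = 2.0
    n_neutral: int = 1500
    mutation_budget: int = 3000
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(SOPE_CATEGORY_MIX)
    )
    deletion_fraction: float = 0.10
    point_sub_rate_gc4: float = 0.043
    point_sub_rate_gc2: float = 0.01
    at_bias: float = 0.75
    neutral_gc2_multiplier: float = 3.0
    gc4_target: float = 0.60
    gc12: float = 0.50
    intergenic_gc: float = 0.45
    spacer_mean: float = 300.0
    spacer_shape: float = 2.0
    is_catalog: list[str] | None = None

    def __post_init__(self) -> None:
        mix = {}
        for k, v in self.category_mix.items():
            mix[_CATEGORY_ALIASES.get(k, k)] = float(v)
        unknown = set(mix) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown event categories {sorted(unknown)}")
        self.category_mix = {c: mix.get(c, 0.0) for c in CATEGORIES}
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix sums to {total}, expected 1")
        if self.n_neutral > self.n_genes:
            raise ValueError("n_neutral must be <= n_genes")
        if self.length_mean < 6:
            raise ValueError("mean ORF length below 6 bases is unsatisfiable")
        for name in (
            "deletion_fraction",
            "point_sub_rate_gc4",
            "point_sub_rate_gc2",
            "at_bias",
            "gc4_target",
            "gc12",
            "intergenic_gc",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ErosionConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TruthTable:
    """Ground truth of one erosion run.

    ``genes``: per gene — is_neutral, fate (intact/pseudogene/absent),
    ancestral_length, n_events.  ``events``: one row per injected disrupting
    mutation, positions in ancestral gene coordinates.  ``substitutions``:
    per-site log of background point substitutions in genic sequence.
    """

    genes: pd.DataFrame
    events: pd.DataFrame
    substitutions: pd.DataFrame
    n_intergenic_subs: int = 0

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
        self.substitutions.to_csv(
            outdir / "truth_substitutions.tsv", sep="\t", index=False
        )


def make_is_element(rng: np.random.Generator, length: int = 1002) -> str:
    """One synthetic IS-like element: random core flanked by a 25-bp inverted
    repeat, the classic architecture of bacterial insertion sequences."""
    ir = rng.choice(_BASES, size=25)
    core = rng.choice(_BASES, size=length - 50)
    seq = b"".join(ir) + b"".join(core) + revcomp(b"".join(ir).decode()).encode()
    return seq.decode()


# ---------------------------------------------------------------------------
# Ancestral genome


def _sample_codons(rng: np.random.Generator, n: int, gc12: float, gc4: float) -> str:
    """Sample ``n`` interior codons; third-position G+C content = ``gc4``.

    Stop codons are rejected and resampled; because all three stop codons lie
    in the TA*/TG* (non-fourfold) families, rejection leaves the realized
    G+C at fourfold-degenerate sites equal to ``gc4`` in expectation.
    """
    if n == 0:
        return ""
    out = np.empty((n, 3), dtype="S1")
    todo = np.arange(n)
    while todo.size:
        m = todo.size
        for col, gc in ((0, gc12), (1, gc12), (2, gc4)):
            is_gc = rng.random(m) < gc
            pick = rng.integers(0, 2, size=m)
            # GC -> G or C ; AT -> A or T
            col_bases = np.where(is_gc, np.where(pick == 0, b"G", b"C"),
                                 np.where(pick == 0, b"A", b"T"))
            out[todo, col] = col_bases
        joined = out[todo].view("S3").ravel()
        bad = np.isin(joined, np.array([s.encode() for s in STOPS]))
        todo = todo[bad]
    return out.tobytes().decode()


def _sample_lengths(rng: np.random.Generator, cfg: ErosionConfig) -> np.ndarray:
    raw = rng.gamma(cfg.length_shape, cfg.length_mean / cfg.length_shape, cfg.n_genes)
    lengths = 3 * np.maximum(3, np.rint(raw / 3).astype(int))
    return lengths


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    is_gc = rng.random(n) < gc
    pick = rng.integers(0, 2, size=n)
    arr = np.where(is_gc, np.where(pick == 0, b"G", b"C"),
                   np.where(pick == 0, b"A", b"T"))
    return arr.tobytes().decode()


def generate_ancestral(config: ErosionConfig) -> GenomeAnnotation:
    """Generate the ancestral genome: codon-structured ORFs on one contig,
    separated by intergenic spacers of configurable G+C.

    Every ORF begins with ATG, ends with a stop codon, and contains no
    internal stop.  Gene lengths (including the stop codon) are gamma draws
    rounded to codons.  Strands alternate at random; minus-strand genes are
    stored reverse-complemented in the contig, so strand-corrected loading is
    exercised end-to-end.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    lengths = _sample_lengths(rng, config)
    n = config.n_genes
    n_digits = len(str(n))
    parts: list[str] = []
    orfs: list[OrfRecord] = []
    pos = 0  # 0-based running position
    contig_id = "chr1"
    for i in range(n):
        spacer_len = max(
            20, int(round(rng.gamma(config.spacer_shape, config.spacer_mean / config.spacer_shape)))
        )
        spacer = _random_bases(rng, spacer_len, config.intergenic_gc)
        parts.append(spacer)
        pos += spacer_len
        L = int(lengths[i])
        n_interior = L // 3 - 2
        coding = (
            "ATG"
            + _sample_codons(rng, n_interior, config.gc12, config.gc4_target)
            + STOPS[rng.integers(0, 3)]
        )
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(coding if strand == "+" else revcomp(coding))
        orfs.append(
            OrfRecord(
                gene_id=f"g{i:0{n_digits}d}",
                contig_id=contig_id,
                start=pos + 1,
                end=pos + L,
                strand=strand,
                sequence=coding,
            )
        )
        pos += L
    tail_len = max(20, int(round(rng.gamma(config.spacer_shape, config.spacer_mean / config.spacer_shape))))
    parts.append(_random_bases(rng, tail_len, config.intergenic_gc))
    return GenomeAnnotation(
        genome_id="ancestral", contigs={contig_id: "".join(parts)}, orfs=orfs
    )


# ---------------------------------------------------------------------------
# Erosion


def _single_sub_stops(codon: str) -> list[tuple[int, str]]:
    """All (offset, base) single substitutions turning ``codon`` into a stop."""
    hits = []
    for stop in STOPS:
        diff = [k for k in range(3) if codon[k] != stop[k]]
        if len(diff) == 1:
            hits.append((diff[0], stop[diff[0]]))
    return hits


class _GeneState:
    """Mutable per-gene erosion state (events in ancestral coordinates)."""

    __slots__ = ("seq", "events", "occupied", "cur_len")

    def __init__(self, seq: str):
        self.seq = seq
        self.events: list[dict] = []
        self.occupied: list[tuple[int, int]] = []  # ancestral [start, end)
        self.cur_len = len(seq)

    def overlaps(self, start: int, end: int, pad: int = 12) -> bool:
        return any(start < e + pad and s - pad < end for s, e in self.occupied)

    def span_after_terminals(self) -> tuple[int, int]:
        """Remaining [lo, hi) ancestral span after terminal deletions."""
        lo, hi = 0, len(self.seq)
        for ev in self.events:
            if ev["category"] == "five_prime_deletion":
                lo = max(lo, ev["size"])
            elif ev["category"] == "three_prime_deletion":
                hi = min(hi, len(self.seq) - ev["size"])
        return lo, hi


def _place_event(
    rng: np.random.Generator,
    state: _GeneState,
    category: str,
    is_catalog: list[str],
) -> dict | None:
    """Try to realize one disrupting event on a gene; None if no legal
    placement was found (caller then resamples gene/category)."""
    L = len(state.seq)
    if category in ("internal_insertion", "internal_deletion", "is_element"):
        for _ in range(10):
            if category == "internal_deletion":
                size = int(rng.choice(INDEL_LENGTHS))
                if L - 12 - size <= 12:
                    return None
                pos = int(rng.integers(12, L - 12 - size))
                start, end = pos, pos + size
            else:
                if category == "internal_insertion":
                    is_index = None
                    size = int(rng.choice(INDEL_LENGTHS))
                else:
                    is_index = int(rng.integers(0, len(is_catalog)))
                    size = len(is_catalog[is_index])
                if L - 12 <= 12:
                    return None
                pos = int(rng.integers(12, L - 12))
                start, end = pos, pos + 1
            lo, hi = state.span_after_terminals()
            if start < lo + 12 or end > hi - 12:
                continue
            if state.overlaps(start, end):
                continue
            ev = {"category": category, "position": pos, "size": size}
            if category == "is_element":
                ev["is_index"] = is_index
            elif category == "internal_insertion":
                ev["insert"] = _random_bases(rng, size, 0.5)
            state.occupied.append((start, end))
            return ev
        return None
    if category in ("five_prime_deletion", "three_prime_deletion"):
        # refuse a second truncation of the same end; keep >=25% of the gene
        # aligned so truncation never masquerades as whole-gene absence
        if any(ev["category"] == category for ev in state.events):
            return None
        for _ in range(10):
            frac = rng.uniform(0.10, 0.50)
            size = max(int(round(frac * L)), (L + 9) // 10)
            lo, hi = state.span_after_terminals()
            if category == "five_prime_deletion":
                start, end = 0, size
                new_lo, new_hi = size, hi
            else:
                start, end = L - size, L
                new_lo, new_hi = lo, L - size
            if new_hi - new_lo < max(30, int(0.25 * L)):
                continue
            if state.overlaps(start, end):
                continue
            state.occupied.append((start, end))
            return {"category": category, "position": start, "size": size}
        return None
    if category == "nonsense":
        n_codons = L // 3
        if n_codons < 5:
            return None
        for _ in range(30):
            ci = int(rng.integers(2, n_codons - 2))
            start, end = 3 * ci, 3 * ci + 3
            lo, hi = state.span_after_terminals()
            if start < lo + 3 or end > hi - 3 or state.overlaps(start, end):
                continue
            hits = _single_sub_stops(state.seq[start:end])
            if not hits:
                continue
            off, base = hits[int(rng.integers(0, len(hits)))]
            state.occupied.append((start, end))
            return {
                "category": "nonsense",
                "position": start + off,
                "size": 0,
                "new_base": base,
            }
        return None
    raise ValueError(f"unknown category {category!r}")


def _realize_gene(state: _GeneState) -> str:
    """Apply a gene's logged events to its ancestral sequence."""
    seq = state.seq
    # substitutions first (positions unaffected by later indels applied
    # right-to-left in the same ancestral frame)
    for ev in state.events:
        if ev["category"] == "nonsense":
            p = ev["position"]
            seq = seq[:p] + ev["new_base"] + seq[p + 1 :]
    indel_evs = [e for e in state.events if e["category"] != "nonsense"]
    for ev in sorted(indel_evs, key=lambda e: -e["position"]):
        p, size, cat = ev["position"], ev["size"], ev["category"]
        if cat == "internal_deletion":
            seq = seq[:p] + seq[p + size :]
        elif cat in ("five_prime_deletion", "three_prime_deletion"):
            seq = seq[:p] + seq[p + size :]
        elif cat == "internal_insertion":
            seq = seq[:p] + ev["insert"] + seq[p:]
        elif cat == "is_element":
            seq = seq[:p] + ev["is_seq"] + seq[p:]
    return seq


def _site_classes(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(gc4_positions, other_positions) for an ancestral coding sequence.

    gc4: third positions of fourfold-family codons (terminal stop codon never
    qualifies).  other: all remaining positions except the terminal stop
    codon, which is kept inviolate.
    """
    L = len(seq) - len(seq) % 3
    codon_starts = np.arange(0, L - 3, 3)  # exclude terminal codon
    prefixes = np.array([seq[i : i + 2] for i in codon_starts])
    is44 = np.isin(prefixes, list(FOURFOLD_PREFIXES))
    gc4 = codon_starts[is44] + 2
    all_pos = np.arange(L - 3)
    other = np.setdiff1d(all_pos, gc4, assume_unique=False)
    return gc4, other


def _apply_substitutions(
    rng: np.random.Generator,
    seq: str,
    gc4_rate: float,
    other_rate: float,
    at_bias: float,
    blocked: list[tuple[int, int]],
    log: list[tuple[str, int, str, str]] | None,
    gene_id: str = "",
) -> str:
    """Background point substitutions on one coding sequence.

    Degenerate (gc4) sites mutate at ``gc4_rate`` with AT-bias; all other
    coding sites at ``other_rate`` toward a uniform different base, skipping
    changes that would create an in-frame stop (nonsense changes are a
    separate, logged event channel, and intact genes are assumed to remain
    under selection against premature stops).
    """
    if gc4_rate == 0 and other_rate == 0:
        return seq
    gc4, other = _site_classes(seq)
    if blocked:
        blk = np.zeros(len(seq), dtype=bool)
        for s, e in blocked:
            blk[s:e] = True
        gc4 = gc4[~blk[gc4]]
        other = other[~blk[other]]
    arr = bytearray(seq.encode())
    for positions, rate, cls in ((gc4, gc4_rate, "gc4"), (other, other_rate, "other")):
        if rate <= 0 or positions.size == 0:
            continue
        hit = positions[rng.random(positions.size) < rate]
        for p in hit:
            orig = chr(arr[p])
            if cls == "gc4":
                new = _biased_base(rng, orig, at_bias)
            else:
                choices = [b for b in "ACGT" if b != orig]
                new = choices[int(rng.integers(0, 3))]
                cs = 3 * (p // 3)
                codon = bytes(arr[cs : cs + 3]).decode()
                trial = codon[: p - cs] + new + codon[p - cs + 1 :]
                if trial in STOP_CODONS:
                    continue
            arr[p] = ord(new)
            if log is not None:
                log.append((gene_id, cls, int(p), orig, new))
    return arr.decode()


def _biased_base(rng: np.random.Generator, orig: str, at_bias: float) -> str:
    if rng.random() < at_bias:
        pool = [b for b in "AT" if b != orig] or ["A", "T"]
    else:
        pool = [b for b in "GC" if b != orig] or ["G", "C"]
    return pool[int(rng.integers(0, len(pool)))]


def erode(
    ancestral: GenomeAnnotation, config: ErosionConfig
) -> tuple[GenomeAnnotation, TruthTable]:
    """Erode an ancestral genome into a derived symbiont genome.

    Order of operations: (i) whole-gene deletions remove
    ``deletion_fraction × n_neutral`` neutral genes ("absent"); (ii)
    ``mutation_budget`` disrupting events are placed one at a time on the
    remaining neutral genes, gene chosen with probability proportional to its
    current length and category drawn from ``category_mix``; (iii) background
    substitutions are applied to every retained gene and to intergenic
    sequence; (iv) the derived contig and annotation are reassembled and every
    change is logged in the TruthTable.  Non-neutral genes receive background
    substitutions only.
    """
    rng = np.random.default_rng([config.seed, 1])
    mix = config.category_mix
    is_catalog = config.is_catalog
    if mix["is_element"] > 0:
        if is_catalog is None:
            is_catalog = [make_is_element(np.random.default_rng([config.seed, 2]))]
        elif len(is_catalog) == 0:
            raise ValueError(
                "category_mix requests is_element insertions but is_catalog is empty"
            )
    is_catalog = is_catalog or []

    orfs = ancestral.orfs
    n = len(orfs)
    if config.n_neutral > n:
        raise ValueError("n_neutral exceeds number of ancestral genes")
    neutral_idx = rng.choice(n, size=config.n_neutral, replace=False)
    n_del = int(round(config.deletion_fraction * config.n_neutral))
    deleted_idx = set(rng.choice(neutral_idx, size=n_del, replace=False).tolist())
    alive_neutral = [int(i) for i in neutral_idx if i not in deleted_idx]

    states = {i: _GeneState(orfs[i].sequence) for i in alive_neutral}

    # (ii) sequential length-proportional event placement
    cat_names = list(CATEGORIES)
    cat_p = np.array([mix[c] for c in cat_names])
    cur_len = np.array([states[i].cur_len for i in alive_neutral], dtype=float)
    events_log: list[dict] = []
    placed = 0
    # category drawn first, then the host gene (length-proportional) is
    # redrawn until placement succeeds: realized category counts are exactly
    # multinomial(category_mix) even when individual placements collide
    while placed < config.mutation_budget:
        if not alive_neutral:
            raise RuntimeError("no neutral genes left to mutate")
        category = cat_names[int(rng.choice(len(cat_names), p=cat_p))]
        ev = None
        for _ in range(200):
            j = int(rng.choice(len(alive_neutral), p=cur_len / cur_len.sum()))
            gi = alive_neutral[j]
            ev = _place_event(rng, states[gi], category, is_catalog)
            if ev is not None:
                break
        if ev is None:
            raise RuntimeError(
                f"could not place a {category} event; neutral class saturated"
            )
        if ev["category"] == "is_element":
            ev["is_seq"] = is_catalog[ev["is_index"]]
        states[gi].events.append(ev)
        delta = {
            "internal_insertion": ev["size"],
            "is_element": ev["size"],
            "internal_deletion": -ev["size"],
            "five_prime_deletion": -ev["size"],
            "three_prime_deletion": -ev["size"],
            "nonsense": 0,
        }[ev["category"]]
        states[gi].cur_len += delta
        cur_len[j] = states[gi].cur_len
        events_log.append(
            dict(
                gene_id=orfs[gi].gene_id,
                category=ev["category"],
                position=ev["position"],
                size=ev["size"],
            )
        )
        placed += 1

    # (iii) realize derived gene sequences + background substitutions
    sub_log: list[tuple[str, int, str, str]] = []
    neutral_set = set(int(i) for i in neutral_idx)
    derived_seq: dict[int, str] = {}
    for i, orf in enumerate(orfs):
        if i in deleted_idx:
            continue
        state = states.get(i)
        blocked = state.occupied if state else []
        other_rate = config.point_sub_rate_gc2 * (
            config.neutral_gc2_multiplier if i in neutral_set else 1.0
        )
        seq = _apply_substitutions(
            rng,
            orf.sequence,
            config.point_sub_rate_gc4,
            min(other_rate, 1.0),
            config.at_bias,
            blocked,
            sub_log,
            orf.gene_id,
        )
        if state:
            state.seq = seq
            seq = _realize_gene(state)
        derived_seq[i] = seq

    # (iv) reassemble derived contig, walking the ancestral contig in order
    contig_id = next(iter(ancestral.contigs))
    anc_contig = ancestral.contigs[contig_id]
    order = sorted(range(n), key=lambda i: orfs[i].start)
    parts: list[str] = []
    new_orfs: list[OrfRecord] = []
    pos = 0  # 0-based cursor in ancestral contig
    out_pos = 0
    n_inter_subs = 0

    def _intergenic(segment: str) -> str:
        nonlocal n_inter_subs
        if not segment or config.point_sub_rate_gc4 == 0:
            return segment
        arr = bytearray(segment.encode())
        hits = np.flatnonzero(rng.random(len(arr)) < config.point_sub_rate_gc4)
        for p in hits:
            arr[p] = ord(_biased_base(rng, chr(arr[p]), config.at_bias))
        n_inter_subs += len(hits)
        return arr.decode()

    for i in order:
        orf = orfs[i]
        seg = _intergenic(anc_contig[pos : orf.start - 1])
        parts.append(seg)
        out_pos += len(seg)
        pos = orf.end
        if i in deleted_idx:
            continue
        seq = derived_seq[i]
        if len(seq) == 0:
            continue
        parts.append(seq if orf.strand == "+" else revcomp(seq))
        new_orfs.append(
            OrfRecord(
                gene_id=orf.gene_id,
                contig_id=contig_id,
                start=out_pos + 1,
                end=out_pos + len(seq),
                strand=orf.strand,
                sequence=seq,
                cog_category=orf.cog_category,
                is_mobile=orf.is_mobile,
            )
        )
        out_pos += len(seq)
    tail = _intergenic(anc_contig[pos:])
    parts.append(tail)
    derived = GenomeAnnotation(
        genome_id="derived", contigs={contig_id: "".join(parts)}, orfs=new_orfs
    )

    # truth table
    gene_rows = []
    events_per_gene: dict[str, int] = {}
    for ev in events_log:
        events_per_gene[ev["gene_id"]] = events_per_gene.get(ev["gene_id"], 0) + 1
    for i, orf in enumerate(orfs):
        if i in deleted_idx:
            fate = "absent"
        elif events_per_gene.get(orf.gene_id, 0) > 0:
            fate = "pseudogene"
        else:
            fate = "intact"
        gene_rows.append(
            dict(
                gene_id=orf.gene_id,
                is_neutral=i in neutral_set,
                fate=fate,
                ancestral_length=orf.length,
                n_events=events_per_gene.get(orf.gene_id, 0),
            )
        )
    truth = TruthTable(
        genes=pd.DataFrame(gene_rows),
        events=pd.DataFrame(
            events_log, columns=["gene_id", "category", "position", "size"]
        ),
        substitutions=pd.DataFrame(
            sub_log, columns=["gene_id", "site_class", "position", "ref_base", "new_base"]
        ),
        n_intergenic_subs=n_inter_subs,
    )
    return derived, truth


def write_run(
    outdir: str | Path,
    ancestral: GenomeAnnotation,
    derived: GenomeAnnotation,
    truth: TruthTable,
    config: ErosionConfig,
    annotation_format: str = "gff3",
) -> None:
    """Write a full simulated run (genomes, truth, config) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "gff3" if annotation_format == "gff3" else "tsv"
    write_genome(ancestral, outdir / "ancestral.fasta", outdir / f"ancestral.{ext}")
    write_genome(derived, outdir / "derived.fasta", outdir / f"derived.{ext}")
    truth.write(outdir)
    config.to_yaml(outdir / "erosion_config.yaml")
    catalog = config.is_catalog
    if catalog is None and config.category_mix["is_element"] > 0:
        catalog = [make_is_element(np.random.default_rng([config.seed, 2]))]
    if catalog:
        with open(outdir / "is_catalog.fasta", "w") as fh:
            for k, seq in enumerate(catalog):
                fh.write(f">IS{k + 1} synthetic insertion sequence\n{seq}\n")
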
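"""Gene-size statistics of the ortholog classes and retention by COG category.

The size analysis is the footprint of cryptic pseudogenes: under
length-proportional accumulation of disrupting mutations, large genes are
disrupted first, so the mean ancestral size of the pseudogene class exceeds
that of the intact class (delta > 0), while whole-gene deletion is size-
unbiased (absent mean ~ overall mean).  Sizes are always ancestral-ortholog
sizes, including for the pseudogene and absent classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SizeSummary", "size_summary", "retention_by_category"]

_CLASSES = ("all", "intact", "pseudogene", "absent")


@dataclass
class SizeSummary:
    """Per-class n / mean ancestral size / SEM, and the intact-vs-pseudogene
    size difference delta = mean(pseudogene) − mean(intact) in bases."""

    table: pd.DataFrame  # index: class; columns: n, mean, sem
    delta: float
    welch_p: float  # two-sided Welch test of the intact/pseudogene means

    def __getitem__(self, cls: str) -> pd.Series:
        return self.table.loc[cls]


def size_summary(
    statuses: pd.Series | dict[str, str],
    ancestral_lengths: pd.Series | dict[str, int],
    include_mobile: bool = False,
    mobile_flags: dict[str, bool] | None = None,
) -> SizeSummary:
    """Summarize ancestral ORF sizes by classification status.

    ``statuses``: gene_id -> intact|pseudogene|absent; every classified gene
    must have an ancestral length.  Mobile-element genes are excluded unless
    ``include_mobile`` (their retention reflects element proliferation, not
    host-gene selection).  Empty classes report NaN; delta is NaN when either
    the intact or the pseudogene class is empty.
    """
    statuses = pd.Series(statuses, name="status")
    lengths = pd.Series(ancestral_lengths, name="length")
    missing = statuses.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"no ancestral length for genes {list(missing)[:5]}...")
    if not include_mobile and mobile_flags:
        keep = [g for g in statuses.index if not mobile_flags.get(g, False)]
        statuses = statuses.loc[keep]
    df = pd.DataFrame({"status": statuses, "length": lengths.loc[statuses.index]})
    rows = {}
    for cls in _CLASSES:
        sub = df["length"] if cls == "all" else df.loc[df["status"] == cls, "length"]
        n = len(sub)
        rows[cls] = dict(
            n=n,
            mean=float(sub.mean()) if n else float("nan"),
            sem=float(sub.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        )
    table = pd.DataFrame(rows).T[["n", "mean", "sem"]]
    intact = df.loc[df["status"] == "intact", "length"]
    pseudo = df.loc[df["status"] == "pseudogene", "length"]
    if len(intact) and len(pseudo):
        delta = float(pseudo.mean() - intact.mean())
        if len(intact) > 1 and len(pseudo) > 1:
            welch_p = float(stats.ttest_ind(pseudo, intact, equal_var=False).pvalue)
        else:
            welch_p = float("nan")
    else:
        delta = float("nan")
        welch_p = float("nan")
    return SizeSummary(table=table, delta=delta, welch_p=welch_p)


def retention_by_category(
    statuses_by_genome: dict[str, pd.Series | dict[str, str]],
    cog_labels: pd.Series | dict[str, str],
) -> pd.DataFrame:
    """Retention of ancestral orthologs per COG functional category across two
    derived genomes.

    A gene is *retained* in a genome when classified intact there.  Output per
    category: retained_in_both, retained_in_one, lost_or_disrupted_in_both.
    Genes without a COG label fall in the "unassigned" bucket.
    """
    if len(statuses_by_genome) != 2:
        raise ValueError("retention comparison requires exactly two derived genomes")
    (ga, sa), (gb, sb) = statuses_by_genome.items()
    sa = pd.Series(sa)
    sb = pd.Series(sb)
    cog = pd.Series(cog_labels) if not isinstance(cog_labels, pd.Series) else cog_labels
    genes = sa.index.union(sb.index)
    rows: dict[str, dict[str, int]] = {}
    for gid in genes:
        cat = cog.get(gid)
        if cat is None or (isinstance(cat, float) and np.isnan(cat)):
            cat = "unassigned"
        r = rows.setdefault(
            str(cat),
            {"retained_in_both": 0, "retained_in_one": 0, "lost_or_disrupted_in_both": 0},
        )
        n_ret = int(sa.get(gid) == "intact") + int(sb.get(gid) == "intact")
        key = ("lost_or_disrupted_in_both", "retained_in_one", "retained_in_both")[n_ret]
        r[key] += 1
    out = pd.DataFrame(rows).T.sort_index()
    out.index.name = "cog_category"
    out["total"] = out.sum(axis=1)
    return out
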
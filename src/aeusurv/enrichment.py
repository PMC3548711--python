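"""Gene-set statistics: hypergeometric overrepresentation and sign-partition
log-odds enrichment.

Two complementary views of a gene list: (1) classic overrepresentation of a
hit list against a background via the upper hypergeometric tail; (2) for a
genome-wide signed association profile (standardized survival slopes), a
2x2 log-odds ratio per set contrasting positively vs negatively associated
genes, with Fisher's exact p.  Negative log-odds means the set is more
enriched among negatively associated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .caller import bh_fdr
from .io import ValidationError

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeom_enrich",
    "sign_partition_enrich",
]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics: id, description, members)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def restrict(self, background: set[str]) -> "GeneSetCollection":
        """Intersect every set with ``background``; drop empties."""
        out = GeneSetCollection()
        for sid, members in self.sets.items():
            kept = members & background
            if kept:
                out.sets[sid] = kept
                out.names[sid] = self.names.get(sid, sid)
        return out


def read_gmt(path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (set id, description, member genes).

    Duplicate members are stored once; a set with no members is dropped
    with a warning; a line with fewer than two fields raises, naming the
    line number.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"malformed GMT line {lineno}: {line[:50]!r}")
            sid, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                log.warning("GMT line %d: set %s has no members, dropped", lineno, sid)
                continue
            coll.sets[sid] = set(members)
            coll.names[sid] = desc
    return coll


def hypergeom_enrich(
    hits, background, sets: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of ``hits`` per set.

    p = Pr(X >= k) with X ~ Hypergeom(M=len(background), n=set size,
    N=len(hits)); BH-FDR across sets.
    """
    hits = set(hits)
    bg = set(background)
    if not hits <= bg:
        raise ValidationError("hits must be a subset of the background")
    restricted = sets.restrict(bg)
    M, N = len(bg), len(hits)
    rows = []
    for sid, members in restricted.sets.items():
        n = len(members)
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append(
            {
                "set_id": sid,
                "name": restricted.names[sid],
                "hits_in_set": k,
                "set_size": n,
                "n_hits": N,
                "background_size": M,
                "p_raw": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_fdr"] = bh_fdr(df["p_raw"].to_numpy())
        df = df.sort_values("p_raw").reset_index(drop=True)
    return df


def sign_partition_enrich(
    assoc: pd.Series, sets: GeneSetCollection
) -> pd.DataFrame:
    """Signed enrichment of each set by partitioning genes on slope sign.

    ``assoc`` maps gene id -> standardized survival slope (estimate/SE).
    Per set: a = positive-in-set, b = negative-in-set, c = positive-out,
    d = negative-out; natural-log odds ratio ln((a/c)/(b/d)) with the
    Haldane–Anscombe 0.5 correction when any cell is zero; two-sided Fisher
    exact p; BH-FDR across sets.  Genes with slope exactly 0 are excluded
    with a warning.
    """
    assoc = assoc.astype(float)
    if not np.all(np.isfinite(assoc.to_numpy())):
        raise ValidationError("standardized slopes must be finite")
    zero = assoc.index[assoc == 0.0]
    if len(zero):
        log.warning("excluding %d gene(s) with slope exactly 0", len(zero))
        assoc = assoc.drop(zero)
    pos = set(assoc.index[assoc > 0])
    neg = set(assoc.index[assoc < 0])
    bg = pos | neg
    restricted = sets.restrict(bg)
    rows = []
    for sid, members in restricted.sets.items():
        a = len(members & pos)
        b = len(members & neg)
        c = len(pos) - a
        d = len(neg) - b
        if min(a, b, c, d) == 0:
            lor = float(np.log(((a + 0.5) / (c + 0.5)) / ((b + 0.5) / (d + 0.5))))
        else:
            lor = float(np.log((a / c) / (b / d)))
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "set_id": sid,
                "name": restricted.names[sid],
                "positive_in_set": a,
                "negative_in_set": b,
                "positive_out": c,
                "negative_out": d,
                "log_odds_ratio": lor,
                "p_raw": float(p),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_fdr"] = bh_fdr(df["p_raw"].to_numpy())
        df = df.sort_values("p_raw").reset_index(drop=True)
    return df
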
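"""Gene-set enrichment of factor top-gene lists: Fisher test, BH, SEGR.

Each factor's top genes (by squared loading) are tested one-sidedly for
over-representation in user-supplied gene sets (GMT), p-values are
BH-adjusted across factors, and the significant-enrichment ratio (SEGR) —
the fraction of factors with at least one significant set — summarizes how
many factors look biologically coherent.  The universe is the set of genes
in the analysed matrix, not the union of the GMT, since enrichment must be
relative to what could have been selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "fisher_enrich",
    "bh_adjust_and_segr",
    "enrich_factors",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): unique names, non-empty member sets."""

    sets: dict
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name) -> set:
        return self.sets[name]

    def names(self) -> list:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes.

    Lines with no members are skipped with a warning; duplicate members
    within a set are counted once; a duplicated set name is a hard error.
    """
    path = Path(path)
    sets: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        name = parts[0].strip()
        members = [g.strip() for g in parts[2:] if g.strip()]
        if not members:
            warnings.warn(f"{path.name}:{lineno}: set {name!r} is empty, skipped")
            continue
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r} at line {lineno}")
        unique = set(members)
        if len(unique) < len(members):
            warnings.warn(
                f"{path.name}:{lineno}: set {name!r} has duplicated members "
                "(deduplicated)"
            )
        sets[name] = unique
    return GeneSetCollection(sets, str(path))


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in gsc.sets.items():
            fh.write("\t".join([name, "na", *sorted(map(str, members))]) + "\n")


def fisher_enrich(query, gsc: GeneSetCollection, universe) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query list in each set.

    The 2x2 table per set is (in query & in set, in query & out, out of
    query & in set, neither), restricted to the universe; p is the upper
    hypergeometric tail P(X >= overlap).  Query genes outside the universe
    are dropped with a warning; set members outside the universe are
    ignored.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query:
        raise ValueError("empty query")
    stray = query - universe
    if stray:
        warnings.warn(f"{len(stray)} query gene(s) outside the universe dropped")
        query &= universe
        if not query:
            raise ValueError("no query genes remain inside the universe")
    m = len(universe)
    n_query = len(query)
    rows = []
    for name, members in gsc.sets.items():
        in_uni = members & universe
        overlap = len(query & in_uni)
        k_set = len(in_uni)
        # P(X >= overlap), X ~ Hypergeom(M=m, n=k_set, N=n_query)
        p = float(stats.hypergeom.sf(overlap - 1, m, k_set, n_query))
        a = overlap
        b = n_query - overlap
        c = k_set - overlap
        d = m - n_query - c
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append(
            {
                "gene_set": name,
                "overlap": overlap,
                "set_size": k_set,
                "query_size": n_query,
                "universe_size": m,
                "odds_ratio": odds,
                "p_value": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)


def bh_adjust_and_segr(
    tables: dict, alpha: float = 0.05, family: str = "pairs"
) -> tuple[pd.DataFrame, float]:
    """BH correction across factors and the SEGR summary.

    Parameters
    ----------
    tables : dict mapping factor id -> DataFrame from :func:`fisher_enrich`
    alpha : float
        Significance level on the adjusted q-values.
    family : {"pairs", "per_factor_min"}
        The multiple-testing family: all factor x set pairs jointly (the
        conservative default), or one minimum p per factor.

    Returns the combined table (factor, gene_set, ..., q_value,
    significant) and SEGR = significant factors / total factors.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if family not in ("pairs", "per_factor_min"):
        raise ValueError("family must be 'pairs' or 'per_factor_min'")
    frames = []
    for factor, df in tables.items():
        df = df.copy()
        df.insert(0, "factor", factor)
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    if family == "pairs":
        _, q, _, _ = multipletests(combined["p_value"], method="fdr_bh")
        combined["q_value"] = q
    else:
        mins = combined.groupby("factor")["p_value"].min()
        _, qmin, _, _ = multipletests(mins, method="fdr_bh")
        qmap = dict(zip(mins.index, qmin))
        # each factor's minimum-p set inherits the factor-level q; other
        # rows keep a q of 1 (they were not part of the family)
        combined["q_value"] = 1.0
        for factor in mins.index:
            rows = combined["factor"] == factor
            imin = combined.loc[rows, "p_value"].idxmin()
            combined.loc[imin, "q_value"] = qmap[factor]
    combined["significant"] = combined["q_value"] < alpha
    sig_factors = combined.loc[combined["significant"], "factor"].nunique()
    segr = sig_factors / len(tables)
    return combined, float(segr)


def enrich_factors(
    rv,
    gsc: GeneSetCollection,
    fraction: float = 0.01,
    alpha: float = 0.05,
    family: str = "pairs",
) -> tuple[pd.DataFrame, float]:
    """Enrichment of every factor's top-fraction genes; returns (table, SEGR)."""
    from .signatures import top_fraction_genes

    universe = rv.gene_ids
    tables = {
        factor: fisher_enrich(top_fraction_genes(rv, factor, fraction), gsc, universe)
        for factor in rv.factor_ids
    }
    return bh_adjust_and_segr(tables, alpha=alpha, family=family)
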
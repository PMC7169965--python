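"""Family-level summary statistics and tree utilities.

Operates on per-protein annotation tables (one row per protein: best
prion-like LLR, prion-domain counts at both thresholds, RRM count,
disorder percentages, log10 compositional-bias P) and computes the
family/clade-level quantities of interest: threshold pass fractions,
multi-prion-domain fractions, RRM-count distributions, and Pearson
correlations between annotation columns.  Tree utilities prune a clade
from a Newick phylogeny and export per-ring annotation tables for
generic tree viewers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

#: canonical column names and accepted header aliases for annotation tables
COLUMN_ALIASES = {
    "seq_id": ["seq_id", "id", "protein", "identifier"],
    "species": ["species", "organism"],
    "family": ["family", "set"],
    "clade": ["clade", "clade_tag", "lineage"],
    "best_llr": ["best_llr", "llr", "plaac_llr"],
    "n_prion_domains_at_0": ["n_prion_domains_at_0", "prion_count_gt0"],
    "n_prion_domains_at_15": ["n_prion_domains_at_15", "prion_count_ge15"],
    "n_internal_prion_at_0": ["n_internal_prion_at_0", "internal_prion_gt0"],
    "n_rrm": ["n_rrm", "rrm_count", "num_rrm"],
    "pct_disorder_a": ["pct_disorder_a", "iupred_pct", "pct_iupred"],
    "pct_disorder_b": ["pct_disorder_b", "disopred_pct", "pct_disopred"],
    "log10_flps_p": ["log10_flps_p", "flps_log10p", "log10_p"],
}

RING_COLUMNS = [
    "best_llr", "pct_disorder_a", "pct_disorder_b", "n_rrm",
    "n_prion_domains_at_0", "n_prion_domains_at_15", "log10_flps_p",
]


class EmptySelectionError(ValueError):
    """A filter left no rows to summarize."""


def load_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read an annotation TSV, mapping header aliases to canonical names."""
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for col in df.columns:
            if col.lower() in aliases:
                rename[col] = canonical
                break
    return df.rename(columns=rename)


def _filter(rows: pd.DataFrame, clade: Optional[str], family: Optional[str]
            ) -> pd.DataFrame:
    df = rows
    if clade is not None:
        df = df[df["clade"] == clade]
    if family is not None:
        df = df[df["family"] == family]
    if df.empty:
        raise EmptySelectionError(
            f"no rows after filtering (clade={clade!r}, family={family!r})"
        )
    return df


def threshold_fractions(
    rows: pd.DataFrame,
    clade: Optional[str] = None,
    family: Optional[str] = None,
) -> dict:
    """Fractions of proteins passing the two LLR thresholds.

    Returns numerators, denominator, exact fractions and the
    display percentages rounded to integers.
    """
    df = _filter(rows, clade, family)
    n = len(df)
    n_gt0 = int((df["best_llr"] > 0.0).sum())
    n_ge15 = int((df["best_llr"] >= 15.0).sum())
    return {
        "n": n,
        "n_gt0": n_gt0,
        "n_ge15": n_ge15,
        "fraction_gt0": n_gt0 / n,
        "fraction_ge15": n_ge15 / n,
        "pct_gt0": round(100.0 * n_gt0 / n),
        "pct_ge15": round(100.0 * n_ge15 / n),
    }


def multi_prion_fraction(
    rows: pd.DataFrame,
    threshold: str = "ge15",
    clade: Optional[str] = None,
    family: Optional[str] = None,
) -> float:
    """Fraction of proteins with >= 2 prion-like domains at a threshold."""
    col = {"gt0": "n_prion_domains_at_0", "ge15": "n_prion_domains_at_15"}[threshold]
    df = _filter(rows, clade, family)
    return float((df[col] >= 2).sum() / len(df))


def internal_extra_fraction(
    rows: pd.DataFrame,
    clade: Optional[str] = None,
    family: Optional[str] = None,
) -> float:
    """Among extra (beyond-first) prion-like domains at LLR > 0, the
    fraction that are internal in the sequence."""
    df = _filter(rows, clade, family)
    extra = (df["n_prion_domains_at_0"] - 1).clip(lower=0).sum()
    if extra == 0:
        return 0.0
    internal = df["n_internal_prion_at_0"].clip(
        upper=(df["n_prion_domains_at_0"] - 1).clip(lower=0)
    ).sum()
    return float(internal / extra)


def rrm_distribution(rows: pd.DataFrame) -> tuple[dict[int, int], int]:
    """Histogram of RRM counts plus the count of proteins with > 3."""
    counts = rows["n_rrm"].astype(int).value_counts().sort_index()
    hist = {int(k): int(v) for k, v in counts.items()}
    return hist, int((rows["n_rrm"] > 3).sum())


def pearson_r(x: Iterable[float], y: Iterable[float]) -> tuple[float, float, int]:
    """Pearson correlation with two-tailed p; pairwise-complete rows only."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[ok], ya[ok]
    n = xa.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("undefined correlation: a column has zero variance")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p), int(n)


# -- tree utilities ---------------------------------------------------------


def prune_clade(
    tree: dendropy.Tree,
    leaf_ids: Optional[Iterable[str]] = None,
    node_label: Optional[str] = None,
) -> dendropy.Tree:
    """Remove one subtree from a rooted phylogeny.

    The subtree is selected either by an internal-node label or as the
    most recent common ancestor of ``leaf_ids``.  After removal, unary
    internal nodes are collapsed with branch lengths summed, so pairwise
    path lengths among surviving leaves are preserved.  An empty leaf
    set returns an unchanged copy.
    """
    out = tree.clone(depth=1)
    out.is_rooted = True
    if node_label is not None:
        matches = [nd for nd in out if nd.label == node_label]
        if len(matches) != 1:
            raise ValueError(
                f"selector {node_label!r} matched {len(matches)} nodes: "
                f"{[m.label for m in matches]}"
            )
        target = matches[0]
    else:
        ids = sorted(set(leaf_ids or []))
        if not ids:
            return out
        taxa = [t for t in out.taxon_namespace if t.label in ids]
        missing = set(ids) - {t.label for t in taxa}
        if missing:
            raise ValueError(f"selector matched zero nodes for leaves: {sorted(missing)}")
        target = out.mrca(taxa=taxa)
    if target.parent_node is None:
        raise ValueError("cannot prune the root of the tree")
    target.parent_node.remove_child(target)
    out.suppress_unifurcations()
    out.purge_taxon_namespace()
    return out


def export_annotation_rings(rows: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Write one two-column TSV per annotation ring, keyed by seq_id."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for col in RING_COLUMNS:
        if col not in rows.columns:
            continue
        path = outdir / f"ring_{col}.tsv"
        rows[["seq_id", col]].to_csv(path, sep="\t", index=False)
        paths[col] = path
    return paths
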
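"""Body-part enrichment of a DMG list over a gene→organ annotation table.

For each organ the observed count is the number of DMGs annotated to it,
and the expected count is ``|list| * |organ genes| / |background|`` where
the background is every gene appearing in the annotation table.  The
enrichment ratio is observed/expected.  Significance comes from an
empirical null: random gene sets of the same size drawn without
replacement from the background (one-sided, enrichment), with an exact
hypergeometric tail available as an alternative.  Benjamini–Hochberg FDR
is applied across all organs in the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr, mc_p_value

logger = logging.getLogger("tadlink.enrichment")

__all__ = [
    "OrganEnrichmentRow",
    "OrganEnrichmentResult",
    "enrichment_ratio",
    "organ_enrichment_test",
]


@dataclass
class OrganEnrichmentRow:
    organ: str
    observed: int
    expected: float
    enrichment_ratio: float
    p_value: float
    fdr: float
    significant: bool


@dataclass
class OrganEnrichmentResult:
    rows: list[OrganEnrichmentRow]
    list_size: int
    background_size: int
    n_discarded: int  # DMGs absent from the annotation background

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "organ": r.organ,
                    "enrichment_ratio": r.enrichment_ratio,
                    "observed": r.observed,
                    "expected": r.expected,
                    "p_value": r.p_value,
                    "fdr": r.fdr,
                    "significant": r.significant,
                }
                for r in self.rows
            ]
        )


def enrichment_ratio(observed: int, expected: float) -> float:
    """Observed over expected gene count for one organ."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return observed / expected


def _normalize_annotations(annotations) -> pd.DataFrame:
    if isinstance(annotations, pd.DataFrame):
        df = annotations[["gene_id", "organ"]].copy()
    else:
        df = pd.DataFrame(list(annotations), columns=["gene_id", "organ"])
    n0 = len(df)
    df = df.drop_duplicates()
    if len(df) != n0:
        logger.warning("collapsed %d duplicate (gene, organ) annotation rows", n0 - len(df))
    return df


def organ_enrichment_test(
    dmgs: Sequence[str],
    annotations,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    method: str = "permutation",
    fdr_threshold: float = 0.05,
) -> OrganEnrichmentResult:
    """Per-organ enrichment of ``dmgs`` against an annotation table.

    ``annotations`` is a DataFrame with columns gene_id/organ or an
    iterable of (gene_id, organ) pairs.  The test list is intersected
    with the annotation background; genes outside it are discarded and
    counted.  ``method`` is ``"permutation"`` (empirical, one-sided
    enrichment, (r+1)/(n+1) convention) or ``"hypergeometric"`` (exact
    upper tail).
    """
    if method not in ("permutation", "hypergeometric"):
        raise ValueError(f"unknown method {method!r}")
    df = _normalize_annotations(annotations)
    background = np.array(sorted(df["gene_id"].unique()))
    n_bg = background.size
    if n_bg == 0:
        raise ValueError("annotation table is empty")
    gene_pos = {g: i for i, g in enumerate(background)}

    dmg_set = set(dmgs)
    in_bg = sorted(dmg_set & set(background))
    n_discarded = len(dmg_set) - len(in_bg)
    if not in_bg:
        raise ValueError("no DMG appears in the annotation background")
    if n_discarded:
        logger.warning("%d DMGs absent from the annotation background; discarded", n_discarded)
    n_list = len(in_bg)

    organs = sorted(df["organ"].unique())
    membership = np.zeros((len(organs), n_bg), dtype=bool)
    organ_pos = {o: i for i, o in enumerate(organs)}
    membership[
        df["organ"].map(organ_pos).to_numpy(), df["gene_id"].map(gene_pos).to_numpy()
    ] = True
    organ_sizes = membership.sum(axis=1)

    list_idx = np.array([gene_pos[g] for g in in_bg])
    observed = membership[:, list_idx].sum(axis=1)
    expected = n_list * organ_sizes / n_bg

    if method == "hypergeometric":
        p = sps.hypergeom.sf(observed - 1, n_bg, organ_sizes, n_list)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        keys = rng.random((n_draws, n_bg))
        draw_idx = np.argpartition(keys, n_list - 1, axis=1)[:, :n_list]
        indicator = np.zeros((n_draws, n_bg), dtype=np.int64)
        np.put_along_axis(indicator, draw_idx, 1, axis=1)
        draw_counts = indicator @ membership.T.astype(np.int64)  # (n_draws, n_organs)
        p = np.array(
            [
                mc_p_value(int((draw_counts[:, k] >= observed[k]).sum()), n_draws)
                for k in range(len(organs))
            ]
        )
    fdr = bh_fdr(p)

    rows = [
        OrganEnrichmentRow(
            organ=o,
            observed=int(observed[k]),
            expected=float(expected[k]),
            enrichment_ratio=(observed[k] / expected[k]) if expected[k] > 0 else float("nan"),
            p_value=float(p[k]),
            fdr=float(fdr[k]),
            significant=bool(fdr[k] < fdr_threshold),
        )
        for k, o in enumerate(organs)
    ]
    return OrganEnrichmentResult(
        rows=rows, list_size=n_list, background_size=n_bg, n_discarded=n_discarded
    )
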
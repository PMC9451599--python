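"""Curated gene-panel reports over triage scores.

Panels group genes by immune function (antigen processing, complement,
cytokine signaling, ...). A panel report lists, per category, the panel
genes whose SR clears a directional cutoff — conserved (SR at or below a
negative cutoff) or over-mutated (SR at or above a positive cutoff) — sorted
within each category by |SR| descending. A gene assigned to several
categories appears once per category.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError

logger = logging.getLogger(__name__)

DIRECTION_CONSERVED = "conserved"
DIRECTION_OVER_MUTATED = "over_mutated"


def load_panels(path: str | Path) -> dict[str, list[str]]:
    """Load panels from YAML: category -> list of gene symbols."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise ConfigError(f"panel file {path} is empty")
    panels: dict[str, list[str]] = {}
    for category, genes in raw.items():
        if not genes:
            raise ConfigError(f"panel category {category!r} has no genes")
        panels[str(category)] = [str(g) for g in genes]
    return panels


def panel_report(
    scores: pd.DataFrame,
    panels: Mapping[str, Sequence[str]],
    direction: str,
    sr_cutoff: float,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Table of (category, gene_symbol, sr) for panel genes past the cutoff.

    `scores` is a cohort score table indexed by gene_symbol with an "sr"
    column. For direction "conserved" the cutoff must be negative and rows
    satisfy sr <= sr_cutoff; for "over_mutated" it must be positive and rows
    satisfy sr >= sr_cutoff. Symbol matching is case-insensitive; `aliases`
    maps panel synonyms to score-table symbols (e.g. PVRL2 -> NECTIN2).
    Panel genes absent from the scores are logged and skipped.
    """
    if direction == DIRECTION_CONSERVED:
        if sr_cutoff > 0:
            raise ConfigError("conserved reports need a non-positive SR cutoff")
    elif direction == DIRECTION_OVER_MUTATED:
        if sr_cutoff < 0:
            raise ConfigError("over-mutated reports need a non-negative SR cutoff")
    else:
        raise ConfigError(f"unknown direction {direction!r}")

    aliases = {k.upper(): v for k, v in (aliases or {}).items()}
    by_upper = {str(g).upper(): g for g in scores.index}

    rows = []
    for category, genes in panels.items():
        block = []
        for gene in genes:
            key = str(gene).upper()
            key = aliases.get(key, key).upper()
            symbol = by_upper.get(key)
            if symbol is None:
                logger.warning("panel gene %s (%s) not present in score table; skipped", gene, category)
                continue
            sr = float(scores.loc[symbol, "sr"])
            if (direction == DIRECTION_CONSERVED and sr <= sr_cutoff) or (
                direction == DIRECTION_OVER_MUTATED and sr >= sr_cutoff
            ):
                block.append({"category": category, "gene_symbol": symbol, "sr": sr})
        block.sort(key=lambda r: -abs(r["sr"]))
        rows.extend(block)
    return pd.DataFrame(rows, columns=["category", "gene_symbol", "sr"])


def cross_cohort_overlap(report_a: pd.DataFrame, report_b: pd.DataFrame) -> set[str]:
    """Gene symbols meeting the cutoff in both cohort reports."""
    if report_a.empty or report_b.empty:
        return set()
    return set(report_a["gene_symbol"]) & set(report_b["gene_symbol"])
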
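"""Reference tables from the Franklin Bay over-wintering survey.

Clone counts per major taxonomic group for the four 16S rRNA gene libraries
built from late-winter landfast sea ice (horizon I, 25 cm depth, combined
calendar days 74+81) and under-ice seawater (day 35): bacterial libraries
FB04bi (ice) and FB04bw (water), archaeal libraries FB04ai and FB04aw.
These printed counts are inputs to the clone-table arithmetic (taxon
fractions, phylotype overlap) and to cross-checks of the diversity
estimators; no sequence data are required.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "bacterial_clone_counts",
    "archaeal_clone_counts",
    "PHYLOTYPE_OVERLAP",
    "taxon_fraction_percent",
    "distinct_phylotypes",
]

_BACTERIAL = {
    "SAR11": (76, 22),
    "other_Alphaproteobacteria": (5, 3),
    "Gammaproteobacteria": (12, 2),
    "Betaproteobacteria": (2, 1),
    "Deltaproteobacteria": (1, 0),
    "unclassified_Proteobacteria": (1, 0),
    "Flavobacteria": (6, 13),
    "Sphingobacteria": (2, 3),
    "Actinobacteria": (3, 1),
    "Verrucomicrobia": (1, 0),
    "Marine_Group_A": (0, 1),
}

_ARCHAEAL = {
    "Marine_Group_I": (46, 41),
    "Marine_Group_II": (6, 4),
}

#: distinct 16S phylotypes per bacterial library and the shared count
PHYLOTYPE_OVERLAP = {"ice": 28, "water": 22, "shared": 6}


def bacterial_clone_counts() -> pd.DataFrame:
    """Clone counts by taxon for the bacterial ice and seawater libraries."""
    return pd.DataFrame(_BACTERIAL, index=["ice", "water"]).T


def archaeal_clone_counts() -> pd.DataFrame:
    """Clone counts by taxon for the archaeal ice and seawater libraries."""
    return pd.DataFrame(_ARCHAEAL, index=["ice", "water"]).T


def taxon_fraction_percent(
    counts: pd.DataFrame, taxon: str, library: str
) -> float:
    """A taxon's share of one library's clones, as a rounded percentage."""
    total = counts[library].sum()
    if total == 0:
        raise ValueError(f"library {library!r} has no clones")
    return float(round(100.0 * counts.loc[taxon, library] / total))


def distinct_phylotypes(n_a: int, n_b: int, n_shared: int) -> int:
    """Distinct phylotypes across two libraries (inclusion-exclusion)."""
    if n_shared > min(n_a, n_b):
        raise ValueError("shared count exceeds a library's phylotype count")
    return n_a + n_b - n_shared
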
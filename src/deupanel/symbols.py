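"""Symbolic encoding of dose-response expression trajectories.

Each control-normalised ratio is mapped onto a five-symbol alphabet —
strong down (↓), moderate down (↙), stable (→), moderate up (↗), strong up
(↑) — and a gene's (r40, r80, r300) profile becomes a three-symbol triplet
such as (→, ↓, ↗).  With five symbols and three positions the pattern space
holds 5**3 = 125 theoretical trajectories; the census groups genes by
realized triplet and singles out genes whose pattern is shared by no other.

Symbols carry both an ASCII code (D, d, S, u, U, ordered down→up) for
machine parsing and a Unicode arrow for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: ASCII alphabet in monotone order: strong down < moderate down < stable <
#: moderate up < strong up.
ALPHABET = ("D", "d", "S", "u", "U")

UNICODE_ARROWS = {"D": "↓", "d": "↙", "S": "→", "u": "↗", "U": "↑"}
_ARROW_TO_ASCII = {v: k for k, v in UNICODE_ARROWS.items()}

#: Position of each symbol in the monotone order (for the monotonicity property).
SYMBOL_ORDER = {s: i for i, s in enumerate(ALPHABET)}


@dataclass(frozen=True)
class SymbolScheme:
    """Ratio cut-points separating the five trajectory symbols.

    The stable band is closed on both sides ([stable_low, up_mod]); its
    neighbours are half-open and the extremes open, so the five intervals
    partition the positive reals:

        ↓: r < down_mod_low            ↙: down_mod_low <= r < stable_low
        →: stable_low <= r <= up_mod   ↗: up_mod < r <= up_strong
        ↑: r > up_strong

    Keeping "stable" maximal treats ratios within roughly ±17% of the
    control as noise-level, the same reading the cut-points encode.
    """

    up_strong: float = 1.37
    up_mod: float = 1.17
    stable_low: float = 0.82
    down_mod_low: float = 0.70

    def __post_init__(self) -> None:
        if not (0 < self.down_mod_low < self.stable_low < 1 < self.up_mod < self.up_strong):
            raise ValueError(
                "cut-points must satisfy 0 < down_mod_low < stable_low < 1 < up_mod < up_strong"
            )


def encode_symbol(ratio: float, scheme: SymbolScheme | None = None) -> str:
    """Map one positive expression ratio to its trajectory symbol (ASCII code)."""
    scheme = scheme or SymbolScheme()
    r = float(ratio)
    if not np.isfinite(r) or r <= 0:
        raise ValueError(f"ratio must be positive and finite, got {ratio!r}")
    if r < scheme.down_mod_low:
        return "D"
    if r < scheme.stable_low:
        return "d"
    if r <= scheme.up_mod:
        return "S"
    if r <= scheme.up_strong:
        return "u"
    return "U"


def encode_triplet(profile, scheme: SymbolScheme | None = None) -> tuple:
    """Encode an (r40, r80, r300) profile positionwise, in ppm order."""
    values = np.asarray(profile, dtype=float).ravel()
    if values.size != 3:
        raise ValueError("a ratio profile has exactly three components")
    return tuple(encode_symbol(v, scheme) for v in values)


def to_unicode(triplet) -> str:
    """Render an ASCII triplet as arrow glyphs, e.g. ('S','D','u') -> '→ ↓ ↗'."""
    return " ".join(UNICODE_ARROWS[s] for s in triplet)


def from_unicode(text: str) -> tuple:
    """Parse an arrow rendering back into the ASCII triplet."""
    return tuple(_ARROW_TO_ASCII[ch] for ch in text.split())


@dataclass
class PatternCensus:
    """Realized trajectory patterns over a gene set.

    ``patterns`` maps each realized triplet to its member genes (the gene
    lists partition the input); ``ordering`` ranks patterns by descending
    mean r300 of their members, ties broken lexicographically on the triplet.
    """

    patterns: dict
    ordering: list
    mean_r300: dict
    n_theoretical: int = len(ALPHABET) ** 3
    n_observed: int = 0

    def table(self) -> pd.DataFrame:
        rows = []
        for rank, trip in enumerate(self.ordering, start=1):
            genes = self.patterns[trip]
            rows.append({
                "rank": rank,
                "pattern": "".join(trip),
                "pattern_arrows": to_unicode(trip),
                "n_genes": len(genes),
                "mean_r300": self.mean_r300[trip],
                "genes": ",".join(genes),
            })
        return pd.DataFrame(rows)


def census_patterns(triplets: dict, profiles: pd.DataFrame) -> PatternCensus:
    """Group genes by identical triplet and rank patterns by mean r300.

    Parameters
    ----------
    triplets : dict
        gene_id -> 3-tuple of ASCII symbols.
    profiles : DataFrame
        Must contain gene_id and r300 (used for the ordering).
    """
    if not triplets:
        raise ValueError("empty triplet input")
    r300 = profiles.set_index("gene_id")["r300"]
    patterns: dict = {}
    for gene in sorted(triplets):
        patterns.setdefault(tuple(triplets[gene]), []).append(gene)
    mean_r300 = {trip: float(r300.loc[genes].mean()) for trip, genes in patterns.items()}
    ordering = sorted(patterns, key=lambda t: (-mean_r300[t], t))
    return PatternCensus(
        patterns=patterns,
        ordering=ordering,
        mean_r300=mean_r300,
        n_observed=len(patterns),
    )


def find_singletons(census: PatternCensus) -> list:
    """Genes whose triplet is shared by no other gene, sorted by symbol."""
    return sorted(g for genes in census.patterns.values() if len(genes) == 1 for g in genes)


class TrajectoryEncoder(TransformerMixin, BaseEstimator):
    """Transformer mapping an (n, 3) array of ratios to ASCII symbol triplets.

    Stateless; ``fit`` only validates the cut-point scheme.
    """

    def __init__(self, up_strong: float = 1.37, up_mod: float = 1.17,
                 stable_low: float = 0.82, down_mod_low: float = 0.70):
        self.up_strong = up_strong
        self.up_mod = up_mod
        self.stable_low = stable_low
        self.down_mod_low = down_mod_low

    def _scheme(self) -> SymbolScheme:
        return SymbolScheme(self.up_strong, self.up_mod, self.stable_low, self.down_mod_low)

    def fit(self, X, y=None):
        self.scheme_ = self._scheme()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected an (n, 3) array of ratio profiles")
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        scheme = self._scheme()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected an (n, 3) array of ratio profiles")
        out = np.empty(X.shape, dtype="<U1")
        for i in range(X.shape[0]):
            out[i] = encode_triplet(X[i], scheme)
        return out
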
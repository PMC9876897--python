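"""Behavioral representational dissimilarity matrices for reading stimuli.

Each stimulus (a Chinese word, an English word, or a Chinese pinyin
transcription) is decomposed three ways:

* **logo-graphemes** — the smallest semantically indivisible visual units
  (radical-like components for Chinese characters, single letters for
  alphabetic stimuli, tone symbols counted as units for pinyin);
* **phonetic units** — initials / finals / tones for Chinese and pinyin,
  vowels / consonants for English, all position-free;
* **a semantic embedding vector** (e.g. 300-d skip-gram word vectors,
  consumed as data — never trained here).

From these we build one representational dissimilarity matrix (RDM) per
linguistic component and writing system.  The visual and phonological RDMs
use one minus the shared-unit ratio; the semantic RDM uses cosine
dissimilarity.
"""

from __future__ import annotations

import itertools
import unicodedata
import warnings
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("chinese_word", "english_word", "chinese_pinyin")
COMPONENTS = ("logo", "phonology", "semantics")
#: ordinal label coding used by the SVR decoder
CONDITION_LABELS = {"chinese_word": 1, "english_word": 2, "chinese_pinyin": 3}


class InvalidStimulusError(ValueError):
    """Raised when a stimulus decomposition cannot be used."""


def _norm_tokens(units: Iterable[str]) -> tuple[str, ...]:
    # decompositions arrive as text; compare after Unicode NFC normalization
    return tuple(unicodedata.normalize("NFC", str(u)) for u in units)


@dataclass(frozen=True)
class StimulusItem:
    """One reading stimulus with its three feature decompositions."""

    id: str
    condition: str
    logo_units: tuple[str, ...]
    phon_units: tuple[str, ...]
    embedding: np.ndarray

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise InvalidStimulusError(f"unknown condition {self.condition!r}")
        object.__setattr__(self, "logo_units", _norm_tokens(self.logo_units))
        object.__setattr__(self, "phon_units", _norm_tokens(self.phon_units))
        if not self.logo_units or not self.phon_units:
            raise InvalidStimulusError(f"stimulus {self.id!r} has an empty unit multiset")
        emb = np.asarray(self.embedding, dtype=float)
        if not np.all(np.isfinite(emb)) or np.linalg.norm(emb) == 0:
            raise InvalidStimulusError(f"stimulus {self.id!r} embedding is not finite/non-zero")
        object.__setattr__(self, "embedding", emb)


@dataclass
class DissimilarityMatrix:
    """Symmetric n x n dissimilarity matrix with zero diagonal.

    Used for behavioral RDMs (``component`` in logo/phonology/semantics)
    and for local neural RDMs (``component`` = "neural").
    """

    values: np.ndarray
    item_ids: list[str]
    component: str
    condition: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} items")

    @property
    def n(self) -> int:
        return len(self.item_ids)

    def lower_triangle(self) -> np.ndarray:
        """Vectorized strictly-lower triangle (the n(n-1)/2 unique pairs)."""
        return self.values[np.tril_indices(self.n, -1)]

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if not np.all(np.diag(v) == 0):
            raise ValueError("diagonal is not exactly zero")
        tri = self.lower_triangle()
        tri = tri[np.isfinite(tri)]
        hi = 1.0 if self.component == "logo" or self.component == "phonology" else 2.0
        if tri.size and (tri.min() < -1e-12 or tri.max() > hi + 1e-12):
            raise ValueError(f"entries outside [0, {hi}] for component {self.component}")


def overlap_dissimilarity(units_a: Sequence[str], units_b: Sequence[str]) -> float:
    """One minus the shared-unit ratio between two unit multisets.

    The shared count is the multiset intersection (sum over tokens of the
    minimum count on either side) and the denominator is the summed sizes:
    ``1 - s / (|a| + |b|)``.  A pair of words decomposed into 6 and 5 units
    sharing 2 of them scores 1 - 2/11 = 0.818; two six-unit pinyin strings
    sharing one unit score 1 - 1/12 = 0.917.
    """
    a = _norm_tokens(units_a)
    b = _norm_tokens(units_b)
    if not a or not b:
        raise InvalidStimulusError("overlap_dissimilarity requires non-empty multisets")
    shared = sum((Counter(a) & Counter(b)).values())
    return 1.0 - shared / (len(a) + len(b))


def semantic_dissimilarity(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """Cosine dissimilarity 1 - cos(a, b), in [0, 2]."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidStimulusError("embedding dimensions differ")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise InvalidStimulusError("zero-norm embedding vector")
    return float(1.0 - (a @ b) / (na * nb))


def _pair_value(item_a: StimulusItem, item_b: StimulusItem, component: str) -> float:
    if component == "logo":
        return overlap_dissimilarity(item_a.logo_units, item_b.logo_units)
    if component == "phonology":
        return overlap_dissimilarity(item_a.phon_units, item_b.phon_units)
    if component == "semantics":
        return semantic_dissimilarity(item_a.embedding, item_b.embedding)
    raise ValueError(f"unknown component {component!r}")


def build_behavioral_rdm(
    stimuli: Sequence[StimulusItem], component: str, condition: str
) -> DissimilarityMatrix:
    """Build one behavioral RDM over a single writing system.

    Items are taken in stable id order; the diagonal is forced to zero by
    RDM convention (the raw shared-unit formula would give 0.5 for a
    self-pair, but diagonals never enter any analysis).
    """
    items = [s for s in stimuli if s.condition == condition]
    seen_conditions = {s.condition for s in stimuli}
    if condition not in seen_conditions and stimuli:
        raise ValueError(f"no stimuli of condition {condition!r}")
    if len(items) < 2:
        raise ValueError(f"need at least 2 stimuli of condition {condition!r}")
    items = sorted(items, key=lambda s: s.id)
    n = len(items)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = _pair_value(items[i], items[j], component)
        values[i, j] = values[j, i] = d
    out = DissimilarityMatrix(values, [s.id for s in items], component, condition)
    out.validate()
    return out


def build_all_rdms(stimuli: Sequence[StimulusItem]) -> dict[tuple[str, str], DissimilarityMatrix]:
    """All (condition, component) behavioral RDMs present in the stimulus set."""
    out = {}
    for condition in CONDITIONS:
        if not any(s.condition == condition for s in stimuli):
            continue
        for component in COMPONENTS:
            out[(condition, component)] = build_behavioral_rdm(stimuli, component, condition)
    return out


def rdm_correlations(rdms: Sequence[DissimilarityMatrix]) -> pd.DataFrame:
    """Pairwise Spearman correlations between RDMs (lower-triangle vectors).

    Constant RDMs have undefined rank correlation; those pairs are reported
    as NaN with a warning.
    """
    ns = {r.n for r in rdms}
    if len(ns) != 1:
        raise ValueError("RDMs differ in size")
    for a, b in itertools.combinations(rdms, 2):
        # within one writing system items must align; across systems the
        # comparison is positional (items are matched by design, not identity)
        if a.condition == b.condition and a.item_ids != b.item_ids:
            raise ValueError("RDMs differ in item order")
    rows = []
    for i, j in itertools.combinations(range(len(rdms)), 2):
        va, vb = rdms[i].lower_triangle(), rdms[j].lower_triangle()
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            warnings.warn("constant RDM: Spearman correlation undefined, reported as NaN")
            rho, p = np.nan, np.nan
        else:
            res = stats.spearmanr(va, vb)
            rho, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "rdm_a": f"{rdms[i].condition}:{rdms[i].component}",
                "rdm_b": f"{rdms[j].condition}:{rdms[j].component}",
                "spearman_rho": rho,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
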
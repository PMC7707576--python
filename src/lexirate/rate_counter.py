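"""Word gain / loss / turnover counting for sister pairs.

The classification follows a Dollo-style logic: a cognate set arises
once, so its distribution across the family tells us what happened on
the two tip branches since a pair split.

For each concept attested in *both* sisters, every cognate set present
in exactly one sister is one event:

* the set also occurs, at the same concept, in at least one background
  language  -> it was inherited from the common ancestor, so the sister
  lacking it **lost** the word (one loss against that sister);
* the set occurs nowhere else in the family at that concept -> it is an
  innovation on the branch of the sister holding it (one **gain**).

Sets present in both sisters, or absent from both, carry no information
about change since the split.  Concepts unattested in either sister are
skipped: absence of data collection cannot be distinguished from loss.
Each qualifying cognate set is one event regardless of how many synonyms
share the concept.  Turnover = gains + losses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError
from .lexicon_io import CognateMatrix
from .phylo_pairs import SisterPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairEvents:
    """Event counts for one sister pair."""

    pair_id: str
    gains_a: int
    gains_b: int
    losses_a: int
    losses_b: int
    concepts_used: int

    @property
    def gains(self) -> int:
        return self.gains_a + self.gains_b

    @property
    def losses(self) -> int:
        return self.losses_a + self.losses_b

    @property
    def turnover(self) -> int:
        return self.gains + self.losses


def count_pair_events(
    pair: SisterPair,
    matrix: CognateMatrix,
    background: Iterable[str],
    *,
    concept_scoped_background: bool = True,
) -> PairEvents:
    """Classify every informative cognate set for one pair.

    ``concept_scoped_background`` controls whether a background
    occurrence of a cognate set under a *different* concept counts as
    evidence of inheritance (default: it does not — cognacy requires a
    common meaning).  The relaxed mode exists for sensitivity analysis.
    """
    a, b = pair.language_a, pair.language_b
    background = [l for l in background if l not in (a, b)]
    if not background:
        raise DataError("background set is empty: losses would be undetectable")
    for lang in (a, b):
        if lang not in matrix.languages:
            raise DataError(f"pair language {lang!r} not in cognate matrix")

    if not concept_scoped_background:
        family_wide: dict[str, set[str]] = {}
        for lang in background:
            for concept in matrix.concepts:
                family_wide.setdefault(lang, set()).update(matrix.presence(lang, concept))

    gains_a = gains_b = losses_a = losses_b = 0
    concepts_used = 0
    for concept in matrix.concepts:
        if not (matrix.attested(a, concept) and matrix.attested(b, concept)):
            continue
        concepts_used += 1
        set_a = matrix.presence(a, concept)
        set_b = matrix.presence(b, concept)
        for cog in set_a ^ set_b:
            if concept_scoped_background:
                inherited = any(cog in matrix.presence(l, concept) for l in background)
            else:
                inherited = any(cog in family_wide[l] for l in background)
            in_a = cog in set_a
            if inherited:
                # present in one sister and elsewhere: the other sister lost it
                if in_a:
                    losses_b += 1
                else:
                    losses_a += 1
            else:
                # unique to one sister in the whole family: an innovation
                if in_a:
                    gains_a += 1
                else:
                    gains_b += 1
    return PairEvents(
        pair_id=pair.pair_id,
        gains_a=gains_a,
        gains_b=gains_b,
        losses_a=losses_a,
        losses_b=losses_b,
        concepts_used=concepts_used,
    )


def tabulate_events(
    pairs: Sequence[SisterPair],
    matrix: CognateMatrix,
    *,
    background: Iterable[str] | None = None,
    concept_scoped_background: bool = True,
) -> pd.DataFrame:
    """One :class:`PairEvents` row per pair.

    Default background policy: for each pair, every other language in the
    matrix (including other pairs' members) serves as background.  An
    explicit ``background`` set overrides this, with the pair's own
    members always excluded.
    """
    seen: set[str] = set()
    for p in pairs:
        if p.language_a in seen or p.language_b in seen or p.language_a == p.language_b:
            raise DataError(f"pairs are not disjoint at {p.pair_id}")
        seen.update((p.language_a, p.language_b))

    rows = []
    for pair in pairs:
        bg = set(background) if background is not None else set(matrix.languages)
        bg -= {pair.language_a, pair.language_b}
        ev = count_pair_events(
            pair, matrix, bg, concept_scoped_background=concept_scoped_background
        )
        rows.append(
            {
                "pair": ev.pair_id,
                "gains_a": ev.gains_a,
                "gains_b": ev.gains_b,
                "losses_a": ev.losses_a,
                "losses_b": ev.losses_b,
                "gains": ev.gains,
                "losses": ev.losses,
                "turnover": ev.turnover,
                "concepts_used": ev.concepts_used,
            }
        )
    columns = [
        "pair", "gains_a", "gains_b", "losses_a", "losses_b",
        "gains", "losses", "turnover", "concepts_used",
    ]
    table = pd.DataFrame(rows, columns=columns)
    logger.info("tabulated events for %d pairs", len(table))
    return table
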
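"""Valence-lexicon sentiment scoring with social-media emphasis rules.

The compound score follows the standard lexicon-and-rule recipe: each token
found in the valence lexicon contributes its score, adjusted by contextual
rules, and the running sum ``s`` is squashed to ``s / sqrt(s^2 + alpha)``
with ``alpha = 15``, which keeps the compound in ``[-1, +1]``.

Adjustment rules (constants are the community-standard values for this
scorer family):

* a negation token within the 3 preceding tokens flips the valence and
  damps it by ``-0.74``;
* each booster (``very``, ``extremely``, ...) within the 3 preceding tokens
  adds ``0.293`` in the direction of the word's sign;
* an ALL-CAPS sentiment word (in mixed-case text) is amplified by 1.5;
* two or more trailing exclamation marks amplify the final sum by 1.292.

Scoring runs on the raw tweet text because the emphasis cues (caps, ``!``)
are destroyed by cleaning; pass ``use_clean_text=True`` to audit the cleaned
stream instead. An external compound scorer can be plugged in for parity
checks against reference tools.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Mapping, Optional

__all__ = [
    "SentimentResult",
    "SentimentScorer",
    "score",
    "classify",
    "ALPHA",
    "NEGATION_DAMP",
    "BOOSTER_INCR",
    "EXCLAIM_EMPHASIS",
    "CAPS_EMPHASIS",
    "DEFAULT_NEGATIONS",
    "DEFAULT_BOOSTERS",
]

ALPHA = 15.0
NEGATION_DAMP = -0.74
BOOSTER_INCR = 0.293
EXCLAIM_EMPHASIS = 1.292
CAPS_EMPHASIS = 1.5
POSITIVE_THRESHOLD = 0.05
NEGATIVE_THRESHOLD = -0.05
NEGATION_SCOPE = 3

DEFAULT_NEGATIONS = frozenset(
    "not never no none nobody nothing neither nowhere cannot cant dont doesnt "
    "didnt isnt wasnt arent werent wont wouldnt shouldnt couldnt aint".split()
)
DEFAULT_BOOSTERS = frozenset(
    "very extremely really so incredibly absolutely completely totally "
    "utterly hugely super".split()
)

_WORD_RE = re.compile(r"[A-Za-z']+")
_APOSTROPHE_RE = re.compile(r"['’ʼ]")


@dataclass(frozen=True)
class SentimentResult:
    tweet_id: str
    compound: float
    label: str  # negative | neutral | positive


def classify(compound: float) -> str:
    """Three-way polarity label; the +/-0.05 band (inclusive) is neutral's
    complement: compound >= +0.05 is positive, <= -0.05 negative."""
    if not -1.0 <= compound <= 1.0:
        raise ValueError("compound must lie in [-1, +1]")
    if compound >= POSITIVE_THRESHOLD:
        return "positive"
    if compound <= NEGATIVE_THRESHOLD:
        return "negative"
    return "neutral"


class SentimentScorer:
    """Compound scorer over a term -> mean-valence lexicon."""

    def __init__(
        self,
        valence_lexicon: Mapping[str, float],
        negations: frozenset[str] = DEFAULT_NEGATIONS,
        boosters: frozenset[str] = DEFAULT_BOOSTERS,
        apply_rules: bool = True,
        external_scorer: Optional[Callable[[str], float]] = None,
    ) -> None:
        self.lexicon = {k.lower(): float(v) for k, v in valence_lexicon.items()}
        self.negations = negations
        self.boosters = boosters
        self.apply_rules = apply_rules
        self.external_scorer = external_scorer

    # -- scoring ------------------------------------------------------------

    def score(self, text: str) -> float:
        if self.external_scorer is not None:
            return float(self.external_scorer(text))
        raw_words = _WORD_RE.findall(_APOSTROPHE_RE.sub("", text))
        lower_words = [w.lower() for w in raw_words]
        all_caps_text = all(w.isupper() for w in raw_words if w.isalpha()) if raw_words else True
        total = 0.0
        for idx, word in enumerate(lower_words):
            valence = self.lexicon.get(word)
            if valence is None:
                continue
            if self.apply_rules:
                if raw_words[idx].isupper() and len(raw_words[idx]) > 1 and not all_caps_text:
                    valence *= CAPS_EMPHASIS
                window = lower_words[max(0, idx - NEGATION_SCOPE) : idx]
                for prev in window:
                    if prev in self.boosters:
                        valence += math.copysign(BOOSTER_INCR, valence)
                if any(prev in self.negations for prev in window):
                    valence *= NEGATION_DAMP
            total += valence
        if self.apply_rules and re.search(r"!{2,}\s*$", text.strip()):
            total *= EXCLAIM_EMPHASIS
        compound = total / math.sqrt(total * total + ALPHA)
        return max(-1.0, min(1.0, compound))

    def label(self, text: str) -> str:
        return classify(self.score(text))

    def result(self, tweet_id: str, text: str) -> SentimentResult:
        compound = self.score(text)
        return SentimentResult(tweet_id=tweet_id, compound=compound, label=classify(compound))


def score(
    text: str,
    valence_lexicon: Mapping[str, float],
    rules: bool = True,
) -> float:
    """Functional wrapper around :class:`SentimentScorer`."""
    return SentimentScorer(valence_lexicon, apply_rules=rules).score(text)
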
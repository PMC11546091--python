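"""Context validation of candidate pairs through a pluggable text backend.

A backend is any callable prompt -> generated text. Generated answers
follow a leading-indicator convention: the first token must be YES (an
interaction is described in the context) or NO, optionally followed by
a confidence level (high/medium/low) and a free-text explanation. The
shipped mock backend is a deterministic, format-conforming rule system
used for testing the pipeline without a language model; a fine-tuned
instruction model can be plugged in through the same contract.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

from .corpus import InstructionExample

logger = logging.getLogger(__name__)

__all__ = [
    "INTERACTION_VERBS",
    "ValidatorVerdict",
    "ValidatorBackend",
    "MalformedOutputError",
    "MalformedPromptError",
    "BackendTransportError",
    "parse_verdict",
    "validate_pair",
    "MockBackend",
    "mock_backend",
]

# Verb lexicon shared with the synthetic abstract templates: the mock
# backend answers YES only when one of these links the two names within
# a single sentence of the context.
INTERACTION_VERBS: tuple[str, ...] = (
    "binds",
    "phosphorylates",
    "activates",
    "inhibits",
    "regulates",
    "interacts with",
    "forms a complex with",
)


class MalformedOutputError(ValueError):
    """Generated text does not begin with a YES/NO indicator."""

    def __init__(self, raw: str):
        super().__init__(f"generated text lacks a leading YES/NO indicator: {raw[:120]!r}")
        self.raw = raw


class MalformedPromptError(ValueError):
    """The mock backend could not locate the pair names or the context."""


class BackendTransportError(RuntimeError):
    """The backend itself failed; the pair is left unprocessed."""


@dataclass(frozen=True)
class ValidatorVerdict:
    decision: str  # "YES" | "NO"
    confidence: str = "unstated"  # high | medium | low | unstated
    explanation: str = ""
    doc_id: str = ""
    raw_output: str = ""
    malformed: bool = False

    @property
    def is_yes(self) -> bool:
        return self.decision == "YES"


@runtime_checkable
class ValidatorBackend(Protocol):
    deterministic: bool

    def __call__(self, prompt: str) -> str: ...


_CONFIDENCE_RE = re.compile(r"confidence\s*(?:level)?\s*[:\-]?\s*(high|medium|low)", re.I)
_LEADING_RE = re.compile(r"^[\s\W_]*([A-Za-z]+)")


def parse_verdict(generated: str, doc_id: str = "") -> ValidatorVerdict:
    """Parse generated text into a verdict.

    The decision is the leading token (after stripping whitespace and
    punctuation), matched case-insensitively against YES/NO; anything else
    raises :class:`MalformedOutputError`. A confidence phrase is extracted
    when present; the remaining text becomes the explanation.
    """
    if not generated or not generated.strip():
        raise MalformedOutputError(generated or "")
    match = _LEADING_RE.match(generated)
    if match is None or match.group(1).upper() not in ("YES", "NO"):
        raise MalformedOutputError(generated)
    decision = match.group(1).upper()

    remainder = generated[match.end():]
    conf_match = _CONFIDENCE_RE.search(remainder)
    confidence = conf_match.group(1).lower() if conf_match else "unstated"
    if conf_match:
        remainder = remainder[conf_match.end():]
    explanation = remainder.strip(" \t\n.,;:-")
    return ValidatorVerdict(decision=decision, confidence=confidence,
                            explanation=explanation, doc_id=doc_id,
                            raw_output=generated)


def validate_pair(example: InstructionExample,
                  backend: Callable[[str], str]) -> ValidatorVerdict:
    """Run one example through the backend and parse the verdict.

    A malformed generation is retried once; a second failure yields a NO
    verdict with unstated confidence, flagged ``malformed``. Backend
    exceptions are wrapped in :class:`BackendTransportError`.
    """
    raw = ""
    for _attempt in range(2):
        try:
            raw = backend(example.prompt)
        except Exception as exc:  # backend failure, not a format problem
            raise BackendTransportError(
                f"backend failed for pair {example.pair}: {exc}") from exc
        try:
            verdict = parse_verdict(raw, doc_id=example.doc_id)
        except MalformedOutputError:
            logger.warning("malformed output for pair %s; retrying", example.pair)
            continue
        logger.debug("raw backend output for %s: %s", example.pair, raw)
        return verdict
    return ValidatorVerdict(decision="NO", confidence="unstated",
                            explanation="backend output malformed twice",
                            doc_id=example.doc_id, raw_output=raw, malformed=True)


# ---------------------------------------------------------------------------
# Mock backend: deterministic rule system over the prompt text
# ---------------------------------------------------------------------------

_CONTEXT_RE = re.compile(r"^Context:\s*(.*)$", re.M)
_QUESTION_RE = re.compile(
    r"is there an interaction between\s+(.+?)\s+and\s+(.+?)\?", re.I)


def _sentences(text: str) -> list[str]:
    return [s for s in re.split(r"(?<=[.!?])\s+", text) if s.strip()]


def _verb_links(sentence: str, name_a: str, name_b: str) -> str | None:
    """Return the lexicon verb directly linking the two names, if any.

    'Directly' means the text between the two names is exactly one lexicon
    verb; a verb aimed at some other entity ("A binds C ... alongside B")
    does not count.
    """
    low = sentence.lower()
    ia, ib = low.find(name_a.lower()), low.find(name_b.lower())
    if ia < 0 or ib < 0 or ia == ib:
        return None
    left, right = (ia, ib) if ia < ib else (ib, ia)
    first_len = len(name_a) if left == ia else len(name_b)
    between = low[left + first_len:right].strip(" ,;")
    return between if between in INTERACTION_VERBS else None


class MockBackend:
    """Deterministic test double for the fine-tuned validation model.

    Emits a YES verdict when an interaction verb from the fixed lexicon
    links the two queried names inside a single sentence of the prompt's
    context (the last Context/Question pair, i.e. after the few-shot
    blocks); otherwise a NO verdict. Always format-conforming.
    """

    deterministic = True

    def __call__(self, prompt: str) -> str:
        contexts = _CONTEXT_RE.findall(prompt)
        questions = _QUESTION_RE.findall(prompt)
        if not contexts or not questions:
            raise MalformedPromptError("prompt lacks a Context or Question section")
        context = contexts[-1]
        name_a, name_b = questions[-1]
        low = context.lower()
        if name_a.lower() not in low or name_b.lower() not in low:
            raise MalformedPromptError(
                f"names {name_a!r}/{name_b!r} not found in the prompt context")
        for sentence in _sentences(context):
            verb = _verb_links(sentence, name_a, name_b)
            if verb is not None:
                return (
                    f"YES. Confidence: high. The context states that {name_a} "
                    f"{verb} {name_b}, a direct interaction."
                )
        return (
            f"NO. Confidence: high. {name_a} and {name_b} are co-mentioned but "
            f"no sentence of the context describes an interaction between them."
        )


#: module-level instance for callers that want a plain callable
mock_backend = MockBackend()
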
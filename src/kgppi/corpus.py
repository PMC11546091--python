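"""Gold-standard relation corpora and instruction-prompt construction.

Gold documents carry an abstract, entity mentions with character spans,
and typed relations between entities. Positive examples come from
relations typed "PPI"; documents with entity markup but no relation
records are dropped. Each retained pair is rendered as an instruction
prompt: two fixed few-shot blocks (drug-drug, to avoid biasing toward
specific protein pairs), the document context, a question restricted to
the provided context, and a required answer format with a leading
YES/NO indicator, a confidence level, and an explanation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .docstore import DocumentStore

logger = logging.getLogger(__name__)

__all__ = [
    "Entity",
    "Relation",
    "GoldDocument",
    "InstructionExample",
    "CorpusIntegrityError",
    "DEFAULT_FEW_SHOT",
    "build_instruction",
    "parse_gold",
    "pair_negatives",
    "load_corpus",
    "save_corpus",
    "write_examples",
    "read_examples",
]


class CorpusIntegrityError(ValueError):
    """A relation references an entity absent from its document."""


@dataclass(frozen=True)
class Entity:
    mention: str
    entity_id: str
    start: int
    end: int


@dataclass(frozen=True)
class Relation:
    arg1: str
    arg2: str
    relation_type: str


@dataclass
class GoldDocument:
    doc_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)

    def validate(self) -> None:
        ids = {e.entity_id for e in self.entities}
        for ent in self.entities:
            if not (0 <= ent.start <= ent.end <= len(self.text)):
                raise CorpusIntegrityError(
                    f"doc {self.doc_id}: span ({ent.start}, {ent.end}) outside text"
                )
        for rel in self.relations:
            for arg in (rel.arg1, rel.arg2):
                if arg not in ids:
                    raise CorpusIntegrityError(
                        f"doc {self.doc_id}: relation references unknown entity {arg!r}"
                    )

    def entity_name(self, entity_id: str) -> str:
        for ent in self.entities:
            if ent.entity_id == entity_id:
                return ent.mention
        raise KeyError(entity_id)


@dataclass(frozen=True)
class InstructionExample:
    prompt: str
    pair: tuple[str, str]
    label: int  # 1 positive, 0 negative
    doc_id: str


DEFAULT_FEW_SHOT: tuple[str, str] = (
    (
        "Example 1:\n"
        "Context: Co-administration of warfarin with fluconazole markedly increased "
        "prothrombin time, showing that fluconazole inhibits the metabolism of warfarin.\n"
        "Question: Based only on the provided context, is there an interaction between "
        "warfarin and fluconazole?\n"
        "Answer: YES. Confidence: high. The context states that fluconazole inhibits "
        "the metabolism of warfarin, a direct drug-drug interaction."
    ),
    (
        "Example 2:\n"
        "Context: Patients in the cohort received metformin for glycemic control. "
        "A separate arm of the study evaluated atorvastatin for lipid management.\n"
        "Question: Based only on the provided context, is there an interaction between "
        "metformin and atorvastatin?\n"
        "Answer: NO. Confidence: high. The two drugs are only co-mentioned in separate "
        "treatment arms; the context reports no interaction between them."
    ),
)


def build_instruction(context: str, name_a: str, name_b: str,
                      few_shot: Sequence[str] = DEFAULT_FEW_SHOT) -> str:
    """Render the instruction prompt for one candidate pair.

    Order: few-shot blocks, the verbatim context, the context-restricted
    question, the confidence request, the explanation request, and the
    leading YES/NO format instruction.
    """
    if not context:
        raise ValueError("context must be nonempty")
    if not name_a or not name_b:
        raise ValueError("both entity names must be nonempty")
    blocks = list(few_shot)
    parts = [
        *blocks,
        f"Context: {context}",
        (
            f"Question: Based only on the provided context, is there an interaction "
            f"between {name_a} and {name_b}?"
        ),
        "State a confidence level (high, medium, low) for your answer.",
        "Provide a brief explanation for your conclusion.",
        "Your answer must begin with YES or NO.",
    ]
    return "\n\n".join(parts)


def parse_gold(docs: Sequence[GoldDocument], include_negatives: bool = False,
               few_shot: Sequence[str] = DEFAULT_FEW_SHOT) -> list[InstructionExample]:
    """Convert gold documents into labelled instruction examples.

    Documents without any relation record are dropped (entity-only markup
    carries no interaction information). Positives are exactly the pairs
    related by a relation of type "PPI". When ``include_negatives`` is
    set, co-mentioned entity pairs without a PPI relation are emitted as
    negative candidates.
    """
    examples: list[InstructionExample] = []
    for doc in docs:
        doc.validate()
        if not doc.relations:
            continue
        ppi_pairs: set[frozenset[str]] = set()
        for rel in doc.relations:
            if rel.relation_type == "PPI" and rel.arg1 != rel.arg2:
                ppi_pairs.add(frozenset((rel.arg1, rel.arg2)))
        seen: set[frozenset[str]] = set()
        for pair in sorted(ppi_pairs, key=sorted):
            a_id, b_id = sorted(pair)
            name_a, name_b = doc.entity_name(a_id), doc.entity_name(b_id)
            examples.append(InstructionExample(
                prompt=build_instruction(doc.text, name_a, name_b, few_shot),
                pair=(name_a, name_b), label=1, doc_id=doc.doc_id))
            seen.add(pair)
        if include_negatives:
            ids = sorted({e.entity_id for e in doc.entities})
            for i, a_id in enumerate(ids):
                for b_id in ids[i + 1:]:
                    key = frozenset((a_id, b_id))
                    if key in ppi_pairs or key in seen:
                        continue
                    name_a, name_b = doc.entity_name(a_id), doc.entity_name(b_id)
                    examples.append(InstructionExample(
                        prompt=build_instruction(doc.text, name_a, name_b, few_shot),
                        pair=(name_a, name_b), label=0, doc_id=doc.doc_id))
    return examples


def pair_negatives(pairs: Sequence[tuple[str, str]], doc_store: DocumentStore,
                   seed: int = 0,
                   few_shot: Sequence[str] = DEFAULT_FEW_SHOT) -> list[InstructionExample]:
    """Negative examples from non-interacting pairs: one seeded random
    mentioning abstract per pair; pairs with no document are skipped."""
    rng = np.random.default_rng(seed)
    out: list[InstructionExample] = []
    for u, v in pairs:
        docs = doc_store.docs_for_pair(u, v)
        if not docs:
            logger.warning("pair (%s, %s) has no mentioning document; skipped", u, v)
            continue
        doc_id, text = docs[int(rng.integers(len(docs)))]
        out.append(InstructionExample(
            prompt=build_instruction(text, u, v, few_shot),
            pair=(u, v), label=0, doc_id=doc_id))
    return out


# ---------------------------------------------------------------------------
# Serialization: corpus JSON and example JSONL
# ---------------------------------------------------------------------------

def load_corpus(path) -> list[GoldDocument]:
    payload = json.loads(Path(path).read_text())
    docs = []
    for rec in payload["documents"]:
        docs.append(GoldDocument(
            doc_id=rec["doc_id"],
            text=rec["text"],
            entities=[Entity(**e) for e in rec.get("entities", [])],
            relations=[Relation(**r) for r in rec.get("relations", [])],
        ))
    return docs


def save_corpus(docs: Sequence[GoldDocument], path) -> None:
    payload = {"documents": [
        {
            "doc_id": d.doc_id,
            "text": d.text,
            "entities": [vars(e) for e in d.entities],
            "relations": [vars(r) for r in d.relations],
        }
        for d in docs
    ]}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_examples(examples: Sequence[InstructionExample], path) -> None:
    with open(path, "w") as fh:
        for ex in examples:
            fh.write(json.dumps({
                "prompt": ex.prompt, "name_a": ex.pair[0], "name_b": ex.pair[1],
                "label": ex.label, "doc_id": ex.doc_id,
            }, sort_keys=True) + "\n")


def read_examples(path) -> list[InstructionExample]:
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            out.append(InstructionExample(
                prompt=rec["prompt"], pair=(rec["name_a"], rec["name_b"]),
                label=int(rec["label"]), doc_id=rec["doc_id"]))
    return out
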
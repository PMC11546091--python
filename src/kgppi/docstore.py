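"""Abstracted document store: pair -> mentioning abstracts, object -> p-value.

Stands between the pipeline and whatever literature index backs it. The
core ships an in-memory implementation; tests and the synthetic world
populate it directly, keeping every run network-free and deterministic.
"""

from __future__ import annotations

from typing import Iterable, Protocol, runtime_checkable

from .graph import canonical_pair

__all__ = ["DocumentStore", "InMemoryDocumentStore"]


@runtime_checkable
class DocumentStore(Protocol):
    def docs_for_pair(self, u: str, v: str) -> list[tuple[str, str]]:
        """All (doc_id, abstract text) mentioning the canonical pair."""
        ...

    def object_pvalue(self, obj: str, query_term: str) -> float | None:
        """Co-occurrence p-value of an object with a query term, or None."""
        ...


class InMemoryDocumentStore:
    """Deterministic dict-backed store."""

    def __init__(self) -> None:
        self._pair_docs: dict[tuple[str, str], list[tuple[str, str]]] = {}
        self._object_p: dict[tuple[str, str], float] = {}

    def add_document(self, u: str, v: str, doc_id: str, text: str) -> None:
        self._pair_docs.setdefault(canonical_pair(u, v), []).append((doc_id, text))

    def set_object_pvalue(self, obj: str, query_term: str, p: float) -> None:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value must lie in [0, 1], got {p}")
        self._object_p[(obj, query_term)] = p

    def docs_for_pair(self, u: str, v: str) -> list[tuple[str, str]]:
        return list(self._pair_docs.get(canonical_pair(u, v), []))

    def object_pvalue(self, obj: str, query_term: str) -> float | None:
        return self._object_p.get((obj, query_term))

    def pairs(self) -> Iterable[tuple[str, str]]:
        return self._pair_docs.keys()

    def n_documents(self) -> int:
        return sum(len(docs) for docs in self._pair_docs.values())
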
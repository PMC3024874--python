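"""Ordered herbal-formula corpora and their numeric position encoding.

A traditional multi-herb formula is an *ordered* list of herbs: by the
Master-Adviser-Soldier-Guide (MASG) convention, an earlier listing position
means a more central role.  A corpus of m formulae over n distinct herbs is
encoded as two m x n matrices:

* ``A`` — integer positions: ``a_ij`` is the 1-based listing position of herb
  j in formula i, or 0 if the herb is absent.
* ``B`` — relative positions: ``b_ij = a_ij / k_i`` where ``k_i`` is the
  number of herbs in formula i, so the last-listed herb always scores 1 and
  formula length no longer matters.

These matrices are the substrate for all downstream pair scoring: the
between-herb-distance of two herbs in one formula is the absolute difference
of their ``B`` entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

NATURAL_PROPERTIES = ("Cold", "Cool", "Neutral", "Warm", "Hot", "Unknown")


@dataclass(frozen=True)
class Herb:
    """A single herb: stable integer id, canonical name, natural property."""

    herb_id: int
    name: str
    natural_property: str = "Unknown"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("herb name must be non-empty")
        if self.natural_property not in NATURAL_PROPERTIES:
            raise ValueError(
                f"unknown natural property {self.natural_property!r}; "
                f"expected one of {NATURAL_PROPERTIES}"
            )


@dataclass(frozen=True)
class Formula:
    """An ordered formula; position 1 is the first-listed (Master) slot."""

    formula_id: str
    herbs: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.herbs)


def encode_positions(corpus: "FormulaCorpus") -> tuple[np.ndarray, np.ndarray]:
    """Materialise the position matrices (A, B) from the formula lists.

    ``A`` holds 1-based positions (0 = absent); ``B = A / k`` row-wise.
    """
    m, n = len(corpus.formulae), len(corpus.herbs)
    A = np.zeros((m, n), dtype=np.int64)
    for i, f in enumerate(corpus.formulae):
        for pos, hid in enumerate(f.herbs, start=1):
            A[i, hid - 1] = pos
    k = np.array([f.k for f in corpus.formulae], dtype=np.int64)
    B = A / k[:, None]
    return A, B


class FormulaCorpus:
    """An immutable corpus of ordered formulae with position matrices A and B.

    Herb ids are assigned 1..n in first-appearance order so that the same
    input file always yields the same encoding.
    """

    def __init__(self, herbs: Sequence[Herb], formulae: Sequence[Formula]):
        herbs = sorted(herbs, key=lambda h: h.herb_id)
        if [h.herb_id for h in herbs] != list(range(1, len(herbs) + 1)):
            raise ValueError("herb ids must be exactly 1..n with no gaps")
        names = [h.name for h in herbs]
        if len(set(names)) != len(names):
            raise ValueError("herb names must be unique within a corpus")
        valid = set(range(1, len(herbs) + 1))
        for f in formulae:
            if f.k < 1:
                raise ValueError(f"formula {f.formula_id!r} has no herbs")
            if len(set(f.herbs)) != f.k:
                raise ValueError(f"formula {f.formula_id!r} lists a duplicate herb")
            if not set(f.herbs) <= valid:
                raise ValueError(f"formula {f.formula_id!r} references an unknown herb id")
        self.herbs: tuple[Herb, ...] = tuple(herbs)
        self.formulae: tuple[Formula, ...] = tuple(formulae)
        self._name_to_col = {h.name: h.herb_id - 1 for h in self.herbs}
        self.A, self.B = encode_positions(self)

    # -- basic shape -------------------------------------------------------

    @property
    def m(self) -> int:
        """Number of formulae."""
        return len(self.formulae)

    @property
    def n(self) -> int:
        """Number of distinct herbs."""
        return len(self.herbs)

    @property
    def herb_names(self) -> list[str]:
        return [h.name for h in self.herbs]

    def column(self, herb: int | str) -> int:
        """0-based matrix column for a herb given by id (1..n) or name."""
        if isinstance(herb, str):
            try:
                return self._name_to_col[herb]
            except KeyError:
                raise ValueError(f"unknown herb {herb!r}") from None
        if not 1 <= int(herb) <= self.n:
            raise ValueError(f"herb id {herb} out of range 1..{self.n}")
        return int(herb) - 1

    def herb(self, herb: int | str) -> Herb:
        return self.herbs[self.column(herb)]

    def records(self) -> list[tuple[str, list[str]]]:
        """Formulae as (formula_id, ordered herb-name list) records."""
        return [
            (f.formula_id, [self.herbs[h - 1].name for h in f.herbs])
            for f in self.formulae
        ]

    def natural_properties(self) -> dict[str, str]:
        return {h.name: h.natural_property for h in self.herbs}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, Sequence[str]]],
        properties: Mapping[str, str] | None = None,
        dedupe: bool = False,
    ) -> "FormulaCorpus":
        """Build a corpus from (formula_id, ordered herb names) records.

        A herb appearing twice in one record is an error unless ``dedupe``
        is set, in which case the first (more central) occurrence is kept.
        """
        records = list(records)
        if not records:
            raise ValueError("corpus is empty: no formula records")
        properties = dict(properties or {})
        name_to_id: dict[str, int] = {}
        herbs: list[Herb] = []
        formulae: list[Formula] = []
        for fid, names in records:
            fid = str(fid)
            names = [str(nm) for nm in names]
            if not names:
                raise ValueError(f"formula {fid!r} has no herbs")
            if len(set(names)) != len(names):
                if not dedupe:
                    raise ValueError(
                        f"formula {fid!r} lists a duplicate herb; "
                        "pass dedupe=True to keep the first occurrence"
                    )
                seen: set[str] = set()
                names = [nm for nm in names if not (nm in seen or seen.add(nm))]
            ids = []
            for nm in names:
                if not nm:
                    raise ValueError(f"formula {fid!r} contains an empty herb name")
                if nm not in name_to_id:
                    name_to_id[nm] = len(name_to_id) + 1
                    herbs.append(
                        Herb(name_to_id[nm], nm, properties.get(nm, "Unknown"))
                    )
                ids.append(name_to_id[nm])
            formulae.append(Formula(fid, tuple(ids)))
        return cls(herbs, formulae)

    def with_properties(self, properties: Mapping[str, str]) -> "FormulaCorpus":
        """Return a copy with natural-property annotations applied by name."""
        merged = self.natural_properties()
        merged.update(properties)
        return FormulaCorpus.from_records(self.records(), properties=merged)


# -- file formats ----------------------------------------------------------


def load_corpus(
    path: str | Path,
    format: str | None = None,
    dedupe: bool = False,
    properties: Mapping[str, str] | None = None,
) -> FormulaCorpus:
    """Read a formula corpus from TSV or JSON-lines.

    TSV rows are ``formula_id<TAB>herb1|herb2|...`` (order significant);
    JSONL rows are ``{"id": ..., "herbs": [...]}``.  Blank lines and lines
    starting with ``#`` are skipped.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in {".jsonl", ".json"} else "tsv"
    if format not in {"tsv", "jsonl"}:
        raise ValueError(f"unknown corpus format {format!r}")
    records: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if format == "tsv":
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'formula_id<TAB>herb1|herb2|...'"
                    )
                fid, herbs_field = parts
                names = [h.strip() for h in herbs_field.split("|") if h.strip()]
            else:
                rec = json.loads(line)
                fid = rec["id"]
                names = list(rec["herbs"])
            records.append((str(fid), names))
    if not records:
        raise ValueError(f"corpus file {path} contains no formula records")
    return FormulaCorpus.from_records(records, properties=properties, dedupe=dedupe)


def write_corpus(corpus: FormulaCorpus, path: str | Path, format: str = "tsv") -> None:
    """Write a corpus in a form :func:`load_corpus` reads back identically."""
    path = Path(path)
    with open(path, "w") as fh:
        for fid, names in corpus.records():
            if format == "tsv":
                fh.write(f"{fid}\t{'|'.join(names)}\n")
            elif format == "jsonl":
                fh.write(json.dumps({"id": fid, "herbs": names}) + "\n")
            else:
                raise ValueError(f"unknown corpus format {format!r}")


def load_synonym_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``variant<TAB>canonical`` -> mapping."""
    return _two_column_tsv(path, "synonym map")


def load_property_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``herb<TAB>property`` -> mapping."""
    table = _two_column_tsv(path, "property table")
    for herb, prop in table.items():
        if prop not in NATURAL_PROPERTIES:
            raise ValueError(f"herb {herb!r}: unknown natural property {prop!r}")
    return table


def _two_column_tsv(path: str | Path, what: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: {what} rows need two columns")
            out[parts[0].strip()] = parts[1].strip()
    return out


# -- name normalisation ----------------------------------------------------


def _canonical(name: str, mapping: Mapping[str, str]) -> str:
    """Resolve a name through the synonym map, following chains."""
    seen = {name}
    while name in mapping:
        name = mapping[name]
        if name in seen:
            raise ValueError(f"cyclic synonym map involving {name!r}")
        seen.add(name)
    return name


def normalize_names(
    corpus: FormulaCorpus, synonym_map: Mapping[str, str]
) -> FormulaCorpus:
    """Substitute synonym/variant herb names by their canonical form.

    Herbs that become identical are merged.  When merging creates a
    duplicate within one formula, the earliest (most central) position is
    kept and the remaining positions are compacted to 1..k'.
    """
    new_records = []
    for fid, names in corpus.records():
        canon = [_canonical(nm, synonym_map) for nm in names]
        seen: set[str] = set()
        kept = [c for c in canon if not (c in seen or seen.add(c))]
        new_records.append((fid, kept))
    props: dict[str, str] = {}
    for nm, prop in corpus.natural_properties().items():
        if prop != "Unknown":
            props.setdefault(_canonical(nm, synonym_map), prop)
    return FormulaCorpus.from_records(new_records, properties=props)
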
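"""MeSH descriptor vocabulary and the disease branch filter.

MEDLINE articles are indexed with descriptors from the Medical Subject
Headings (MeSH) thesaurus, a poly-hierarchy addressed by dotted tree
numbers (``C04.557.470``).  A descriptor counts as a *disease* when at
least one of its tree numbers falls under the disease branches
C01–C26 (Diseases) or F02/F03 (psychological phenomena / mental
disorders), and its heading is not one of four catch-all terms that are
too unspecific to be informative ("Disease", "Disease Progression",
"Disease Attributes", "Disease Models, Animal").

Vocabularies load from the NLM descriptor XML dialect
(``DescriptorRecordSet``) or from a 3-column TSV fallback
(``name<TAB>ui<TAB>tree1;tree2``) convenient for fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

from lxml import etree

__all__ = [
    "MeshDescriptor",
    "DiseaseBranchFilter",
    "VocabularyError",
    "DEFAULT_DISEASE_PREFIXES",
    "DEFAULT_EXCLUDED_NAMES",
    "is_disease_descriptor",
    "tree_number_under",
    "load_mesh_vocabulary",
    "write_mesh_tsv",
]

#: Tree-number prefixes whose descendants are considered diseases.
DEFAULT_DISEASE_PREFIXES: tuple[str, ...] = tuple(
    f"C{i:02d}" for i in range(1, 27)
) + ("F02", "F03")

#: Catch-all headings excluded for lack of specificity.
DEFAULT_EXCLUDED_NAMES: frozenset[str] = frozenset(
    {"Disease", "Disease Progression", "Disease Attributes", "Disease Models, Animal"}
)


class VocabularyError(ValueError):
    """Raised for malformed or inconsistent vocabulary sources."""


@dataclass(frozen=True)
class MeshDescriptor:
    """One controlled-vocabulary concept.

    Parameters
    ----------
    name : str
        Canonical heading, unique within a vocabulary.
    ui : str
        Descriptor unique identifier (e.g. ``D009369``).
    tree_numbers : tuple of str
        Dot-delimited tree positions; may be empty, in which case the
        descriptor matches no branch.
    """

    name: str
    ui: str
    tree_numbers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise VocabularyError("descriptor name must be non-empty")
        object.__setattr__(self, "tree_numbers", tuple(self.tree_numbers))


def tree_number_under(tree_number: str, prefix: str) -> bool:
    """True iff *tree_number* equals *prefix* or sits below it.

    Matching respects dot boundaries: ``C260.1`` is *not* under ``C26``.
    """
    return tree_number == prefix or tree_number.startswith(prefix + ".")


@dataclass(frozen=True)
class DiseaseBranchFilter:
    """Tree-branch inclusion plus name-based exclusion.

    ``included_prefixes`` are top-level category codes or deeper dot
    paths; ``excluded_names`` are compared exactly (case-sensitive)
    against canonical headings, which are canonical in MeSH.
    """

    included_prefixes: tuple[str, ...] = DEFAULT_DISEASE_PREFIXES
    excluded_names: frozenset[str] = DEFAULT_EXCLUDED_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "included_prefixes", tuple(self.included_prefixes))
        object.__setattr__(self, "excluded_names", frozenset(self.excluded_names))
        if not self.included_prefixes:
            raise VocabularyError("filter needs at least one included prefix")

    def accepts(self, descriptor: MeshDescriptor) -> bool:
        if descriptor.name in self.excluded_names:
            return False
        return any(
            tree_number_under(tn, p)
            for tn in descriptor.tree_numbers
            for p in self.included_prefixes
        )

    def describe(self) -> str:
        """One-line human-readable description (persisted in table headers)."""
        return "prefixes={} excluded={}".format(
            ",".join(self.included_prefixes),
            "|".join(sorted(self.excluded_names)),
        )


def is_disease_descriptor(
    descriptor: MeshDescriptor, branch_filter: DiseaseBranchFilter | None = None
) -> bool:
    """Decide whether *descriptor* counts as a disease.

    Returns True iff the heading is not excluded by name and at least
    one tree number lies under an included branch prefix.
    """
    if branch_filter is None:
        branch_filter = DiseaseBranchFilter()
    return branch_filter.accepts(descriptor)


Source = Union[str, os.PathLike, IO[str]]


def _read_text(source: Source) -> str:
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    text = os.fspath(source)
    # A path on disk; otherwise treat the string as file content.
    if "\n" not in text and "\t" not in text and os.path.exists(text):
        with open(text, "r", encoding="utf-8") as fh:
            return fh.read()
    return text


def load_mesh_vocabulary(source: Source) -> list[MeshDescriptor]:
    """Load descriptors from XML (``DescriptorRecordSet``) or TSV.

    The TSV fallback has three tab-separated columns: name, UI,
    semicolon-joined tree numbers (third column may be empty).  Lines
    starting with ``#`` are comments.

    Raises
    ------
    VocabularyError
        On malformed records (naming the offender) or duplicate
        descriptor names (listing the duplicates).
    """
    text = _read_text(source)
    if text.lstrip().startswith("<"):
        descriptors = _parse_descriptor_xml(text)
    else:
        descriptors = _parse_descriptor_tsv(text)
    seen: dict[str, int] = {}
    for d in descriptors:
        seen[d.name] = seen.get(d.name, 0) + 1
    duplicates = sorted(n for n, c in seen.items() if c > 1)
    if duplicates:
        raise VocabularyError(f"duplicate descriptor names: {', '.join(duplicates)}")
    return descriptors


def _parse_descriptor_xml(text: str) -> list[MeshDescriptor]:
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise VocabularyError(f"malformed descriptor XML: {exc}") from exc
    out = []
    for idx, rec in enumerate(root.iter("DescriptorRecord")):
        name = rec.findtext("DescriptorName/String")
        ui = rec.findtext("DescriptorUI")
        if not name or not ui:
            raise VocabularyError(
                f"descriptor record #{idx + 1} lacks DescriptorName/String or DescriptorUI"
            )
        trees = tuple(
            tn.text.strip()
            for tn in rec.findall("TreeNumberList/TreeNumber")
            if tn.text and tn.text.strip()
        )
        out.append(MeshDescriptor(name=name.strip(), ui=ui.strip(), tree_numbers=trees))
    return out


def _parse_descriptor_tsv(text: str) -> list[MeshDescriptor]:
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise VocabularyError(
                f"line {lineno}: expected 2 or 3 tab-separated columns, got {len(parts)}"
            )
        name, ui = parts[0].strip(), parts[1].strip()
        trees: tuple[str, ...] = ()
        if len(parts) == 3 and parts[2].strip():
            trees = tuple(t.strip() for t in parts[2].split(";") if t.strip())
        if not name:
            raise VocabularyError(f"line {lineno}: empty descriptor name")
        out.append(MeshDescriptor(name=name, ui=ui, tree_numbers=trees))
    return out


def write_mesh_tsv(descriptors: Iterable[MeshDescriptor], path: str | os.PathLike) -> None:
    """Write the 3-column TSV fallback format."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in descriptors:
            fh.write(f"{d.name}\t{d.ui}\t{';'.join(d.tree_numbers)}\n")
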
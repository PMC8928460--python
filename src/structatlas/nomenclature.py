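"""Hierarchical nomenclature of structure names with inheritable colors.

A nomenclature is a tree where each entry represents a brain structure with a
name and, possibly, an 8-bit RGB display color.  Colors are inherited: an
entry without one resolves to its nearest colored ancestor.  Names are unique
tree-wide so that label→entry resolution is never ambiguous.
"""

from __future__ import annotations

from typing import Iterator, Optional

from .errors import NotFound

RGB = tuple[int, int, int]


class NomenclatureEntry:
    """One named structure in the tree, with optional color and children."""

    __slots__ = ("name", "color", "children")

    def __init__(self, name: str, color: Optional[RGB] = None, children=None):
        if not name:
            raise ValueError("entry name cannot be empty")
        if color is not None:
            color = tuple(int(c) for c in color)
            if len(color) != 3 or any(not 0 <= c <= 255 for c in color):
                raise ValueError(f"color must be an RGB triple in [0, 255], got {color}")
        self.name = str(name)
        self.color = color
        self.children: list[NomenclatureEntry] = list(children or [])

    def walk(self) -> Iterator["NomenclatureEntry"]:
        """Depth-first traversal of the subtree rooted here (inclusive)."""
        yield self
        for child in self.children:
            yield from child.walk()

    def __repr__(self):
        return f"NomenclatureEntry({self.name!r}, {len(self.children)} children)"


class Nomenclature:
    """Tree of structure names; indexes name→entry and name→parent.

    Raises ``ValueError`` at construction if a name occurs twice anywhere in
    the tree.
    """

    def __init__(self, root: NomenclatureEntry, version: str = "1.0"):
        self.root = root
        self.version = str(version)
        self._entries: dict[str, NomenclatureEntry] = {}
        self._parent: dict[str, Optional[str]] = {}
        self._index(root, None)

    def _index(self, entry: NomenclatureEntry, parent: Optional[str]):
        if entry.name in self._entries:
            raise ValueError(f"duplicate name in nomenclature: {entry.name!r}")
        self._entries[entry.name] = entry
        self._parent[entry.name] = parent
        for child in entry.children:
            self._index(child, entry.name)

    # -- queries ----------------------------------------------------------
    def contains(self, name: str) -> bool:
        """True iff ``name`` occurs anywhere in the tree."""
        return name in self._entries

    def entry(self, name: str) -> NomenclatureEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise NotFound(f"name {name!r} not in nomenclature") from None

    def resolve_color(self, name: str) -> Optional[RGB]:
        """Entry's own color, else the nearest colored ancestor's, else None."""
        current: Optional[str] = name
        if current not in self._entries:
            raise NotFound(f"name {name!r} not in nomenclature")
        while current is not None:
            color = self._entries[current].color
            if color is not None:
                return color
            current = self._parent[current]
        return None

    def subtree_labels(self, name: str) -> set[str]:
        """All names in the subtree rooted at ``name``, inclusive."""
        return {e.name for e in self.entry(name).walk()}

    def leaf_names(self) -> list[str]:
        """Names of leaf entries, in tree order."""
        return [e.name for e in self.root.walk() if not e.children]

    def names(self) -> set[str]:
        return set(self._entries)

    def __len__(self):
        return len(self._entries)

    def __contains__(self, name):
        return self.contains(name)
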
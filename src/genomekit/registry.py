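"""Species registry: alias-based lookup of annotation stores.

A registry maps common names ("human") onto species handles.  Collection
stores — multi-species stores whose declared name contains the term
"collection" — expose each contained species as a separate handle scoped by
its species id.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

from .model import ModelError
from .store import Store


class RegistryError(ModelError):
    pass


@dataclass(frozen=True)
class SpeciesHandle:
    """One species inside one store; all queries are scoped by species_id."""
    store: Store
    species_id: int
    species_name: str
    store_name: str


class Registry:
    def __init__(self):
        self._handles: dict[str, SpeciesHandle] = {}
        self._aliases: dict[str, set[str]] = {}

    def register_store(self, store: Store, store_name: str = "core") -> list[SpeciesHandle]:
        """Register every species in a store; returns the new handles.

        Single-species stores register their one species; collection stores
        (store_name containing "collection") register one handle per
        contained species, discovered from the meta table.
        """
        species = store.species()
        if not species:
            raise RegistryError(f"store {store_name!r} declares no species")
        if "collection" not in store_name and len(species) > 1:
            raise RegistryError(
                f"store {store_name!r} holds {len(species)} species but is not "
                f"named as a collection")
        handles = []
        for species_id, name in species:
            handle = SpeciesHandle(store, species_id, name, store_name)
            if name in self._handles:
                raise RegistryError(f"species {name!r} registered twice")
            self._handles[name] = handle
            self.add_alias(name, name)
            handles.append(handle)
        return handles

    def add_alias(self, alias: str, species_name: str) -> None:
        self._aliases.setdefault(alias.casefold(), set()).add(species_name)

    def load_aliases(self, path) -> int:
        """Flat key-value config: one ``alias = species_name`` per line;
        blank lines and '#' comments ignored."""
        n = 0
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise RegistryError(f"malformed registry line: {line!r}")
                alias, species = (part.strip() for part in line.split("=", 1))
                self.add_alias(alias, species)
                n += 1
        return n

    def lookup(self, alias: str) -> SpeciesHandle:
        """Case-insensitive alias resolution to a species handle."""
        key = alias.casefold()
        names = sorted(self._aliases.get(key, ()))
        if len(names) > 1:
            raise RegistryError(
                f"alias {alias!r} is ambiguous between species: {', '.join(names)}")
        if names:
            name = names[0]
            if name in self._handles:
                return self._handles[name]
            raise RegistryError(
                f"alias {alias!r} points at unregistered species {name!r}")
        near = difflib.get_close_matches(key, list(self._aliases), n=3, cutoff=0.6)
        hint = f"; nearest matches: {', '.join(sorted(near))}" if near else ""
        raise RegistryError(f"unknown species alias {alias!r}{hint}")
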
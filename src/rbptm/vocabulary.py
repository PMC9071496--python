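"""Controlled vocabulary of PTM type labels.

Source catalogs spell modification types inconsistently
("Phospho", "phosphorylated", "ubiquitylation", ...); harmonization maps
every incoming label onto one canonical label via a versioned synonym
table shipped with the package. Labels that map to nothing are never
silently passed through — callers drop them with a logged count.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ValidationError

_NORM_RE = re.compile(r"[^a-z0-9]+")


def _squash(label):
    """Lower-case and strip separators so 'N6-malonyllysine' and
    'n6 malonyl lysine' normalize identically."""
    return _NORM_RE.sub("", label.strip().lower())


@dataclass
class PTMVocabulary:
    labels: tuple
    compatibility: dict = field(default_factory=dict)
    synonyms: dict = field(default_factory=dict)
    nonenzymatic: frozenset = frozenset()
    version: int = 0

    def __post_init__(self):
        problems = []
        if len(set(self.labels)) != len(self.labels):
            problems.append("duplicate labels in vocabulary")
        for label, aas in self.compatibility.items():
            if aas is not None and len(aas) == 0:
                problems.append(f"{label}: empty compatibility set")
        if problems:
            raise ValidationError(problems)
        self._lookup = {_squash(l): l for l in self.labels}
        for syn, canon in self.synonyms.items():
            self._lookup[_squash(syn)] = canon

    def __contains__(self, label):
        return label in self.labels

    def __iter__(self):
        return iter(self.labels)

    def normalize(self, raw):
        """Map a raw catalog label to its canonical form, or None if the
        label is unknown."""
        return self._lookup.get(_squash(raw))

    def compatible_residues(self, label):
        """Amino acids a PTM type can occur on, or None for 'any'."""
        return self.compatibility.get(label)

    @classmethod
    def from_yaml(cls, path):
        data = yaml.safe_load(Path(path).read_text())
        types = data.get("types", {})
        compat = {
            label: (None if aas is None else frozenset(aas)) for label, aas in types.items()
        }
        return cls(
            labels=tuple(types),
            compatibility=compat,
            synonyms=dict(data.get("synonyms", {})),
            nonenzymatic=frozenset(data.get("nonenzymatic", [])),
            version=int(data.get("version", 0)),
        )


def default_vocabulary():
    """The vocabulary shipped with the package."""
    ref = resources.files("rbptm") / "data" / "vocabulary.yaml"
    with resources.as_file(ref) as path:
        return PTMVocabulary.from_yaml(path)
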
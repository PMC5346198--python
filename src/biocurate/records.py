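"""Typed records produced by the document parsers.

Optional bibliographic fields use ``None`` as the absent marker; the
question-mark rendering seen on the command line ("DOI: ?") is applied
only by the card renderer, never stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

#: Clinical code vocabularies (cerebral-aneurysm case records).
SEX_CODES = ("F", "M")
ANEURYSM_TYPES = ("TER", "LAT")   # terminal / lateral
STATUS_CODES = ("U", "R")         # unruptured / ruptured


@dataclass(frozen=True)
class Author:
    """One article author; ``fore_name`` holds a forename or initials."""

    last_name: str
    fore_name: str

    def display(self) -> str:
        return f"{self.last_name} {self.fore_name}".strip()


@dataclass(frozen=True)
class Article:
    """A bibliographic record from a literature repository."""

    pmid: str
    title: str
    authors: tuple[Author, ...] = ()
    journal: Optional[str] = None
    volume: Optional[str] = None
    issue: Optional[str] = None
    year: Optional[int] = None
    doi: Optional[str] = None
    abstract: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.pmid or not self.pmid.isdigit():
            raise ValueError(f"pmid must be a non-empty digit string, got {self.pmid!r}")

    @property
    def first_author(self) -> Optional[str]:
        return self.authors[0].display() if self.authors else None


@dataclass(frozen=True)
class Disease:
    """A disease hit on a compendium search-results page."""

    name: str
    card_link: str

    def __post_init__(self) -> None:
        if not self.card_link.startswith("/card/"):
            raise ValueError(
                f"card link must start with '/card/', got {self.card_link!r}"
            )


@dataclass(frozen=True)
class BioModel:
    """A mathematical-model record; the XML payload is kept opaque."""

    model_id: str
    description: Optional[str] = None
    document: bytes = b""

    def __post_init__(self) -> None:
        import re

        if not re.fullmatch(r"BIOMD\d{10}", self.model_id):
            raise ValueError(
                f"model id must be BIOMD + 10 digits, got {self.model_id!r}"
            )


@dataclass
class AneurysmCase:
    """A clinical aneurysm case: patient data, geometry and risk score.

    ``geometry_ref`` is a path/key to the STL-derived surface mesh stored
    beside the database; ``risk_score`` is the scalar output of an external
    rupture-risk criterion.  Associations to articles, diseases and models
    are held per relation label and persisted alongside the case.
    """

    patient_id: str
    sex: str
    age: int
    aneurysm_type: str
    location: str
    status: str
    geometry_ref: Optional[str] = None
    risk_score: Optional[float] = None
    associations: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for violation in case_violations(
            self.sex, self.age, self.aneurysm_type, self.status
        ):
            raise ValueError(violation)


def case_violations(sex: str, age, aneurysm_type: str, status: str) -> list[str]:
    """Invariant checks shared by the constructor and the table parser."""
    out = []
    if sex not in SEX_CODES:
        out.append(f"sex must be one of {SEX_CODES}, got {sex!r}")
    if not isinstance(age, (int, np.integer)) or isinstance(age, bool) or age < 0:
        out.append(f"age must be a non-negative integer, got {age!r}")
    if aneurysm_type not in ANEURYSM_TYPES:
        out.append(
            f"aneurysm type must be one of {ANEURYSM_TYPES}, got {aneurysm_type!r}"
        )
    if status not in STATUS_CODES:
        out.append(f"status must be one of {STATUS_CODES}, got {status!r}")
    return out


class TriMesh:
    """Triangle-soup surface mesh as read from an STL file.

    Stored as float64 arrays: ``vertices`` with shape (n_facets, 3, 3)
    (facet, corner, xyz) and per-facet ``normals`` with shape (n_facets, 3).
    Coordinates keep the length units of the source file.
    """

    def __init__(self, vertices: np.ndarray, normals: np.ndarray):
        vertices = np.asarray(vertices, dtype=np.float64)
        normals = np.asarray(normals, dtype=np.float64)
        if vertices.ndim != 3 or vertices.shape[1:] != (3, 3):
            raise ValueError("vertices must have shape (n, 3, 3)")
        if normals.shape != (vertices.shape[0], 3):
            raise ValueError("normals must have shape (n, 3)")
        if not (np.isfinite(vertices).all() and np.isfinite(normals).all()):
            raise ValueError("mesh coordinates must be finite")
        self.vertices = vertices
        self.normals = normals

    @property
    def n_facets(self) -> int:
        return self.vertices.shape[0]

    def __len__(self) -> int:
        return self.n_facets

    def __eq__(self, other) -> bool:
        if not isinstance(other, TriMesh):
            return NotImplemented
        return (
            self.vertices.shape == other.vertices.shape
            and np.array_equal(self.vertices, other.vertices)
            and np.array_equal(self.normals, other.normals)
        )

    def allclose(self, other: "TriMesh", atol: float = 1e-6) -> bool:
        """Coordinate-wise agreement within ``atol`` (dialect comparisons)."""
        return (
            self.vertices.shape == other.vertices.shape
            and np.allclose(self.vertices, other.vertices, atol=atol, rtol=0.0)
            and np.allclose(self.normals, other.normals, atol=atol, rtol=0.0)
        )


def finite_or_error(score: float) -> float:
    score = float(score)
    if not math.isfinite(score):
        raise ValueError(f"risk score must be finite, got {score!r}")
    return score
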
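"""STL surface-mesh reading and writing (ASCII and binary dialects).

The reader auto-detects the dialect: an ASCII file starts with ``solid``
and contains ``facet`` keywords; a binary file is an 80-byte header, a
little-endian uint32 facet count, and fifty bytes per facet (normal,
three vertices as float32 triples, and a two-byte attribute).  The binary
facet count is checked against the payload length before any facet is
decoded, so truncated downloads fail loudly.

Both dialects are also written here (the fixture generator and the
geometry side-files of the case store use the writers).
"""

from __future__ import annotations

import io
import re
import struct

import numpy as np

from .errors import FormatError, TruncationError
from .records import TriMesh

_BINARY_FACET_DTYPE = np.dtype(
    [
        ("normal", "<f4", (3,)),
        ("vertices", "<f4", (3, 3)),
        ("attr", "<u2"),
    ]
)

# numeric token, including non-finite spellings so the finiteness
# invariant (not the tokenizer) rejects them
_ASCII_FLOAT = r"[-+]?(?:[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?|nan|inf(?:inity)?)"
_FACET_RE = re.compile(
    rf"facet\s+normal\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})\s+"
    rf"outer\s+loop\s+"
    rf"vertex\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})\s+"
    rf"vertex\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})\s+"
    rf"vertex\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})\s+"
    rf"endloop\s+endfacet",
    re.IGNORECASE,
)


def _looks_ascii(payload: bytes) -> bool:
    head = payload.lstrip()[:5].lower()
    return head == b"solid" and b"facet" in payload.lower()


def load_stl(payload: bytes) -> TriMesh:
    """Load an STL payload into a :class:`TriMesh`, auto-detecting dialect.

    Raises :class:`TruncationError` when a binary facet count is
    inconsistent with the payload length, and :class:`FormatError` when
    neither dialect is recognised.
    """
    if not isinstance(payload, bytes):
        raise TypeError("STL payload must be bytes")
    if _looks_ascii(payload):
        return _load_ascii(payload)
    return _load_binary(payload)


def _load_ascii(payload: bytes) -> TriMesh:
    text = payload.decode("utf-8", errors="replace")
    matches = _FACET_RE.findall(text)
    n_declared = len(re.findall(r"\bfacet\s+normal\b", text, re.IGNORECASE))
    if n_declared != len(matches):
        raise FormatError(
            f"ASCII STL declares {n_declared} facets but only "
            f"{len(matches)} parsed completely"
        )
    values = np.array(matches, dtype=np.float64).reshape(-1, 12)
    normals = values[:, :3]
    vertices = values[:, 3:].reshape(-1, 3, 3)
    return TriMesh(vertices=vertices, normals=normals)


def _load_binary(payload: bytes) -> TriMesh:
    if len(payload) < 84:
        raise FormatError(
            "payload matches neither STL dialect (too short for binary, "
            "no ASCII 'solid'/'facet' keywords)"
        )
    (count,) = struct.unpack_from("<I", payload, 80)
    expected = 84 + 50 * count
    if len(payload) != expected:
        raise TruncationError(
            f"binary STL header declares {count} facets "
            f"({expected} bytes) but payload holds {len(payload)} bytes"
        )
    facets = np.frombuffer(payload, dtype=_BINARY_FACET_DTYPE, count=count, offset=84)
    return TriMesh(
        vertices=facets["vertices"].astype(np.float64),
        normals=facets["normal"].astype(np.float64),
    )


def write_stl_ascii(mesh: TriMesh, name: str = "mesh") -> bytes:
    """Serialise a mesh as ASCII STL (float values in repr precision)."""
    out = io.StringIO()
    out.write(f"solid {name}\n")
    for normal, triangle in zip(mesh.normals, mesh.vertices):
        out.write(f"  facet normal {normal[0]:.9e} {normal[1]:.9e} {normal[2]:.9e}\n")
        out.write("    outer loop\n")
        for vertex in triangle:
            out.write(f"      vertex {vertex[0]:.9e} {vertex[1]:.9e} {vertex[2]:.9e}\n")
        out.write("    endloop\n")
        out.write("  endfacet\n")
    out.write(f"endsolid {name}\n")
    return out.getvalue().encode("ascii")


def write_stl_binary(mesh: TriMesh, header: bytes = b"") -> bytes:
    """Serialise a mesh as little-endian binary STL."""
    facets = np.zeros(mesh.n_facets, dtype=_BINARY_FACET_DTYPE)
    facets["normal"] = mesh.normals.astype(np.float32)
    facets["vertices"] = mesh.vertices.astype(np.float32)
    head = (header[:80]).ljust(80, b"\0")
    return head + struct.pack("<I", mesh.n_facets) + facets.tobytes()


def unit_cube() -> TriMesh:
    """The axis-aligned unit cube triangulated into 12 facets (two per
    face), a convenient geometric reference object."""
    v = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    # Each face: two triangles with outward normal.
    faces = [
        ((0, 1, 3), (0, 3, 2), (-1, 0, 0)),
        ((4, 6, 7), (4, 7, 5), (1, 0, 0)),
        ((0, 4, 5), (0, 5, 1), (0, -1, 0)),
        ((2, 3, 7), (2, 7, 6), (0, 1, 0)),
        ((0, 2, 6), (0, 6, 4), (0, 0, -1)),
        ((1, 5, 7), (1, 7, 3), (0, 0, 1)),
    ]
    vertices = []
    normals = []
    for tri_a, tri_b, normal in faces:
        for tri in (tri_a, tri_b):
            vertices.append(v[list(tri)])
            normals.append(normal)
    return TriMesh(vertices=np.array(vertices), normals=np.array(normals, dtype=float))
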
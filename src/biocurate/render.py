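"""Command-line record cards.

Entities print as dashed cards, one block of labelled lines between
39-hyphen separators, e.g.::

    ---------------------------------------
    ID: 10227670
    TITLE: Three dimensional analysis of microaneurysms in the human diabetic retina.
    AUTHOR: Moore JJ
    JOURNAL: Journal of anatomy 194 (Pt 1)(?), 1999, DOI: ?
    ---------------------------------------

Absent optional values render as ``?``.  Rendering is pure text
formatting: no store access, and every printed value is recoverable from
the entity itself.
"""

from __future__ import annotations

from .errors import RenderError
from .records import AneurysmCase, Article, BioModel, Disease

SEPARATOR = "-" * 39
UNKNOWN = "?"

#: Model descriptions longer than this many characters are truncated with
#: a trailing ellipsis on the card (full text is stored untruncated).
DESCRIPTION_LIMIT = 80


def _opt(value) -> str:
    return UNKNOWN if value is None else str(value)


def _article_lines(article: Article) -> list[str]:
    journal = (
        f"JOURNAL: {_opt(article.journal)} {_opt(article.volume)}"
        f"({_opt(article.issue)}), {_opt(article.year)}, DOI: {_opt(article.doi)}"
    )
    return [
        f"ID: {article.pmid}",
        f"TITLE: {article.title}",
        f"AUTHOR: {_opt(article.first_author)}",
        journal,
    ]


def _disease_lines(disease: Disease) -> list[str]:
    return [f"Name: {disease.name}", "Link at MalaCards:", disease.card_link]


def _biomodel_lines(model: BioModel, limit: int) -> list[str]:
    description = model.description
    if description is None:
        rendered = UNKNOWN
    elif len(description) > limit:
        rendered = description[:limit] + "…"
    else:
        rendered = description
    return [f"Id: {model.model_id}", f"Description: {rendered}"]


def _case_lines(case: AneurysmCase) -> list[str]:
    return [
        f"Patient ID: {case.patient_id}",
        f"SEX: {case.sex}, AGE: {case.age}",
        f"Aneurysm type: {case.aneurysm_type}, location:{case.location}, "
        f"status: {case.status}",
    ]


def card_lines(entity, description_limit: int = DESCRIPTION_LIMIT) -> list[str]:
    if isinstance(entity, Article):
        return _article_lines(entity)
    if isinstance(entity, Disease):
        return _disease_lines(entity)
    if isinstance(entity, BioModel):
        return _biomodel_lines(entity, description_limit)
    if isinstance(entity, AneurysmCase):
        return _case_lines(entity)
    raise RenderError(f"no card layout for {type(entity).__name__}")


def render_card(entity, description_limit: int = DESCRIPTION_LIMIT) -> str:
    """Render one entity as a dashed record card (separator, labelled
    lines, separator)."""
    lines = [SEPARATOR, *card_lines(entity, description_limit), SEPARATOR]
    return "\n".join(line.rstrip() for line in lines)


def render_cards(entities, description_limit: int = DESCRIPTION_LIMIT) -> str:
    """Render a sequence of entities as a single block, adjacent cards
    sharing their separator line (the command-line listing format)."""
    entities = list(entities)
    if not entities:
        return SEPARATOR
    lines = [SEPARATOR]
    for entity in entities:
        lines.extend(line.rstrip() for line in card_lines(entity, description_limit))
        lines.append(SEPARATOR)
    return "\n".join(lines)
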
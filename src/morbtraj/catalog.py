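"""WHO ICD-10 block/chapter catalog and code-to-block mapping.

Diagnoses are analysed at the level of ICD-10 *blocks* (e.g. ``I20-I25``,
ischaemic heart diseases), each of which belongs to exactly one *chapter*
(e.g. ``I00-I99``, circulatory system).  The packaged catalog covers the
disease chapters A00–N99; chapters O–Z describe obstetrics, perinatal and
congenital conditions, symptoms, injuries and healthcare interactions and
are excluded from analysis.  The catalog is user-replaceable via
:func:`load_catalog` to support coding dialects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["BlockCatalog", "load_catalog", "map_code_to_block", "UNMAPPED"]

#: Sentinel returned for syntactically valid codes outside the catalog.
UNMAPPED = "unmapped"

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]?$")
_BLOCK_RE = re.compile(r"^[A-Z][0-9]{2}-[A-Z][0-9]{2}$")


def _code_key(code3: str) -> int:
    """Order a 3-character ICD-10 code as letter-major integer."""
    return (ord(code3[0]) - ord("A")) * 100 + int(code3[1:3])


@dataclass(frozen=True)
class BlockCatalog:
    """Inclusive code-range lookup table from 3-character codes to blocks.

    Parameters
    ----------
    table:
        One row per block with columns ``block_id``, ``block_label``,
        ``chapter_id``, ``chapter_label``.  ``block_id`` must have the form
        ``"A00-A09"``; ranges within a chapter may not overlap.
    """

    table: pd.DataFrame
    _starts: list[int] = field(default_factory=list, repr=False)
    _ends: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        rows = self.table.sort_values("block_id", kind="stable").reset_index(drop=True)
        starts, ends = [], []
        for bid in rows["block_id"]:
            if not _BLOCK_RE.match(bid):
                raise ValueError(f"malformed block_id in catalog: {bid!r}")
            lo, hi = bid.split("-")
            starts.append(_code_key(lo))
            ends.append(_code_key(hi))
        for i in range(1, len(starts)):
            if starts[i] <= ends[i - 1]:
                raise ValueError(
                    f"overlapping catalog ranges: {rows['block_id'][i - 1]!r} "
                    f"and {rows['block_id'][i]!r}"
                )
        object.__setattr__(self, "table", rows)
        object.__setattr__(self, "_starts", starts)
        object.__setattr__(self, "_ends", ends)

    @property
    def block_ids(self) -> list[str]:
        return list(self.table["block_id"])

    def chapter_of(self, block_id: str) -> str:
        hit = self.table.loc[self.table["block_id"] == block_id, "chapter_id"]
        if hit.empty:
            raise KeyError(f"unknown block {block_id!r}")
        return hit.iloc[0]

    def lookup(self, code: str) -> tuple[str, str]:
        """Map an ICD-10 code (or a block id) to ``(block_id, chapter_id)``.

        Returns ``(UNMAPPED, UNMAPPED)`` for valid codes outside the catalog.
        Passing an existing ``block_id`` returns it unchanged, so normalised
        records round-trip through the mapping.
        """
        code = code.strip().upper()
        if _BLOCK_RE.match(code):
            row = self.table.loc[self.table["block_id"] == code]
            if row.empty:
                return UNMAPPED, UNMAPPED
            return code, row["chapter_id"].iloc[0]
        if not _CODE_RE.match(code):
            raise ValueError(f"malformed ICD-10 code: {code!r}")
        key = _code_key(code[:3])
        # linear scan over ~150 sorted ranges; bisect is overkill here
        for start, end, (bid, chap) in zip(
            self._starts, self._ends, self.table[["block_id", "chapter_id"]].itertuples(index=False)
        ):
            if start <= key <= end:
                return bid, chap
        return UNMAPPED, UNMAPPED


def load_catalog(path: str | Path | None = None) -> BlockCatalog:
    """Load the packaged WHO A00–N99 catalog, or a user CSV with the same columns."""
    if path is None:
        with resources.files("morbtraj.data").joinpath("icd10_blocks.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    required = {"block_id", "block_label", "chapter_id", "chapter_label"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    return BlockCatalog(table)


def map_code_to_block(code: str, catalog: BlockCatalog) -> tuple[str, str]:
    """Return ``(block_id, chapter_id)`` for *code*; ``(UNMAPPED, UNMAPPED)`` if outside."""
    return catalog.lookup(code)
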
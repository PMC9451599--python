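"""Minimal HGVSp (protein-change) parsing for hotspot matching.

Handles the notations that occur in MC3 MAF ``HGVSp_Short`` / ``HGVSp``
columns: one-letter substitutions (p.G12D), nonsense (p.Q61*), three-letter
forms (p.Gln61His), frameshifts (p.G12fs, p.T286Lfs*97), in-frame indels
(p.E746_A750del, p.P772_H773insX) and duplications. Anything else parses to
None rather than raising; hotspot rules treat unparseable changes as
non-matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Sec": "U",
}

_AA3_RE = re.compile("|".join(AA3_TO_1))

# ref residue, 1-based position, then the remainder (alt residue, fs, del, ...)
_CHANGE_RE = re.compile(r"^p\.\(?([A-Z*])(\d+)(.*?)\)?$")


def normalize_protein_change(hgvsp: str | None) -> str | None:
    """Collapse three-letter residue codes to one-letter form.

    ``p.Gln61His`` -> ``p.Q61H``; one-letter input passes through unchanged.
    """
    if hgvsp is None:
        return None
    hgvsp = hgvsp.strip()
    if not hgvsp:
        return None
    return _AA3_RE.sub(lambda m: AA3_TO_1[m.group(0)], hgvsp)


@dataclass(frozen=True)
class ProteinChange:
    """A parsed protein change: reference residue, position, and alteration."""

    ref: str            # one-letter reference residue at `position`
    position: int       # 1-based residue position (first residue for ranges)
    alt: str            # "" for pure positional events (del/ins/fs ranges)
    is_substitution: bool  # single-residue replacement (incl. nonsense)

    @property
    def is_synonymous(self) -> bool:
        return self.is_substitution and self.alt == self.ref


def parse_protein_change(hgvsp: str | None) -> ProteinChange | None:
    """Parse an HGVSp string; return None when it cannot be interpreted."""
    norm = normalize_protein_change(hgvsp)
    if norm is None:
        return None
    m = _CHANGE_RE.match(norm)
    if not m:
        return None
    ref, pos, rest = m.group(1), int(m.group(2)), m.group(3)
    # single-residue substitution: alt is exactly one residue letter or stop
    if re.fullmatch(r"[A-Z*]", rest):
        return ProteinChange(ref=ref, position=pos, alt=rest, is_substitution=True)
    if rest == "=":  # HGVS synonymous shorthand
        return ProteinChange(ref=ref, position=pos, alt=ref, is_substitution=True)
    # frameshift, in-frame del/ins/dup, ranges: positional event, no single alt
    return ProteinChange(ref=ref, position=pos, alt="", is_substitution=False)


def protein_position(hgvsp: str | None) -> int | None:
    """First residue position named by an HGVSp string, or None."""
    parsed = parse_protein_change(hgvsp)
    return parsed.position if parsed else None
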
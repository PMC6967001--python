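"""CDR identification from sequence anchor rules.

The six hypervariable loops (L1-L3 on the light chain, H1-H3 on the heavy
chain) are located without any numbering scheme, purely from the conserved
framework anchors that flank them: the FR1/FR3 cysteines, the tryptophan
that opens FR2, fixed framework block lengths between loops, and the
C-terminal W-G-x-G / F-G-x-G framework-4 motifs. The rule constants live in
``data/cdr_rules.yaml``.

All offsets are 0-based half-open relative to the owning chain.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import load_cdr_rules
from .errors import CdrError


@dataclass(frozen=True)
class CdrRegion:
    """One CDR: chain-relative half-open offsets and the subsequence."""

    name: str
    start: int
    stop: int
    sequence: str

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class CdrSet:
    """The six CDRs of an Fv, keyed L1, L2, L3, H1, H2, H3."""

    l1: CdrRegion
    l2: CdrRegion
    l3: CdrRegion
    h1: CdrRegion
    h2: CdrRegion
    h3: CdrRegion

    def regions(self) -> list[CdrRegion]:
        return [self.l1, self.l2, self.l3, self.h1, self.h2, self.h3]

    def concatenated(self) -> str:
        return "".join(r.sequence for r in self.regions())


def _find_anchor_cys(chain: str, window: tuple[int, int], chain_name: str,
                     region: str) -> int:
    lo, hi = window
    idx = chain.find("C", lo, hi)
    if idx < 0:
        raise CdrError(
            f"{chain_name}: anchor Cys for {region} not found in "
            f"positions [{lo}, {hi})"
        )
    return idx

def _match_motif(chain: str, pos: int, motif: str) -> bool:
    if pos + len(motif) > len(chain):
        return False
    return all(m == "x" or chain[pos + i] == m for i, m in enumerate(motif))


def _scan_length(chain: str, start: int, rule: dict, chain_name: str,
                 region: str) -> int:
    """Return the region stop: the smallest permitted length whose right

    flank matches the rule's terminator residue or motif."""
    lo, hi = rule["length_range"]
    terminator = rule.get("terminator")
    motif = rule.get("end_motif")
    for length in range(lo, hi + 1):
        stop = start + length
        if stop > len(chain):
            break
        if terminator is not None and stop < len(chain) \
                and chain[stop] in terminator:
            return stop
        if motif is not None and _match_motif(chain, stop, motif):
            return stop
    what = f"terminator {terminator}" if terminator else f"motif {motif}"
    raise CdrError(
        f"{chain_name}: no {region} end with length in [{lo}, {hi}] "
        f"followed by {what}"
    )


def _find_chain_cdrs(chain: str, rules: dict, chain_name: str,
                     names: tuple[str, str, str]) -> list[CdrRegion]:
    n1, n2, n3 = names
    r1, r2, r3 = rules[n1], rules[n2], rules[n3]

    cys = _find_anchor_cys(chain, tuple(r1["cys_window"]), chain_name, n1)
    start1 = cys + r1["start_after_cys"]
    stop1 = _scan_length(chain, start1, r1, chain_name, n1)

    start2 = stop1 + r2["gap_after_previous"]
    stop2 = start2 + r2["length_range"][0]
    if r2["length_range"][0] != r2["length_range"][1]:
        stop2 = _scan_length(chain, start2, r2, chain_name, n2)
    if stop2 > len(chain):
        raise CdrError(f"{chain_name}: chain too short for {n2}")

    start3 = stop2 + r3["gap_after_previous"]
    cys_off = r3["cys_offset_before_start"]
    if start3 - cys_off < 0 or start3 - cys_off >= len(chain) \
            or chain[start3 - cys_off] != "C":
        raise CdrError(
            f"{chain_name}: anchor Cys expected {cys_off} residue(s) "
            f"before {n3} start (position {start3 - cys_off})"
        )
    stop3 = _scan_length(chain, start3, r3, chain_name, n3)

    regions = [
        CdrRegion(n1, start1, stop1, chain[start1:stop1]),
        CdrRegion(n2, start2, stop2, chain[start2:stop2]),
        CdrRegion(n3, start3, stop3, chain[start3:stop3]),
    ]
    for reg, rule in zip(regions, (r1, r2, r3)):
        lo, hi = rule["length_range"]
        if not lo <= len(reg) <= hi:
            raise CdrError(
                f"{chain_name}: {reg.name} length {len(reg)} outside "
                f"permitted range [{lo}, {hi}]"
            )
    return regions


def find_cdrs(vh: str, vl: str) -> CdrSet:
    """Locate all six CDRs in a VH/VL chain pair.

    Raises :class:`CdrError` naming the chain and region if an anchor motif
    is missing or a located region violates its length rule.
    """
    rules = load_cdr_rules()
    l1, l2, l3 = _find_chain_cdrs(vl, rules["light"], "VL", ("L1", "L2", "L3"))
    h1, h2, h3 = _find_chain_cdrs(vh, rules["heavy"], "VH", ("H1", "H2", "H3"))
    return CdrSet(l1=l1, l2=l2, l3=l3, h1=h1, h2=h2, h3=h3)
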
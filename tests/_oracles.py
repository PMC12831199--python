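"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written from the published rule statements with
plain Python/`math` (no numpy, no shared helpers), so that agreement
with the package is a genuine dual-route check.
"""

from __future__ import annotations

import math
import re


# ---------------------------------------------------------------------------
# secondary structure: enumerate all residue pairs, apply the electrostatic
# hydrogen-bond energy and the turn/bridge rules directly
# ---------------------------------------------------------------------------

def _pos(residue, name):
    atom = residue.atom(name)
    return None if atom is None else tuple(float(x) for x in atom.position)


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def brute_force_ss(chain) -> str:
    """Three-class labels by direct enumeration of every residue pair."""
    res = chain.residues
    n = len(res)
    if n < 3:
        return "C" * n

    breaks = set()
    for i in range(n - 1):
        ca1, ca2 = _pos(res[i], "CA"), _pos(res[i + 1], "CA")
        if ca1 is None or ca2 is None or _dist(ca1, ca2) > 4.5:
            breaks.add(i)

    hydrogens = {}
    for i in range(1, n):
        if res[i].name3.upper() == "PRO" or (i - 1) in breaks:
            continue
        n_i = _pos(res[i], "N")
        c_p, o_p = _pos(res[i - 1], "C"), _pos(res[i - 1], "O")
        if n_i is None or c_p is None or o_p is None:
            continue
        co = [o - c for o, c in zip(o_p, c_p)]
        norm = math.sqrt(sum(x * x for x in co))
        if norm == 0:
            continue
        hydrogens[i] = tuple(n_i[k] - 1.01 * co[k] / norm for k in range(3))

    def hbond(donor, acceptor):
        if abs(donor - acceptor) < 2 or donor not in hydrogens:
            return False
        n_d = _pos(res[donor], "N")
        c_a, o_a = _pos(res[acceptor], "C"), _pos(res[acceptor], "O")
        if n_d is None or c_a is None or o_a is None:
            return False
        h_d = hydrogens[donor]
        r_on, r_ch = _dist(o_a, n_d), _dist(c_a, h_d)
        r_oh, r_cn = _dist(o_a, h_d), _dist(c_a, n_d)
        if min(r_on, r_ch, r_oh, r_cn) < 0.5:
            return True  # clamped to -9.9 kcal/mol, below the cutoff
        energy = 0.084 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
        return energy < -0.5

    def unbroken(i, j):
        return not any(k in breaks for k in range(min(i, j), max(i, j)))

    turns = {m: set() for m in (3, 4, 5)}
    for m in (3, 4, 5):
        for i in range(n - m):
            if hbond(i + m, i) and unbroken(i, i + m):
                turns[m].add(i)

    helix = set()
    for m in (3, 4, 5):
        for i in range(1, n - m):
            if i in turns[m] and (i - 1) in turns[m]:
                helix.update(range(i, i + m))

    bridge = set()
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            par = (hbond(j, i - 1) and hbond(i + 1, j)) or (
                hbond(i, j - 1) and hbond(j + 1, i)
            )
            anti = (hbond(j, i) and hbond(i, j)) or (
                hbond(j + 1, i - 1) and hbond(i + 1, j - 1)
            )
            if par or anti:
                bridge.add(i)
                bridge.add(j)

    return "".join(
        "H" if i in helix else ("E" if i in bridge else "C") for i in range(n)
    )


# ---------------------------------------------------------------------------
# motif scan: overlapping regex with lookahead
# ---------------------------------------------------------------------------

def regex_scan_starts(sequence: str, bracket_spec: str, offset: int = 1) -> list[int]:
    """1-based start positions of all (overlapping) motif occurrences."""
    pattern = re.compile(rf"(?=({bracket_spec}))")
    return [m.start() + offset for m in pattern.finditer(sequence)]
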
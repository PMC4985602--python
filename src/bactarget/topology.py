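"""Hydropathy-based transmembrane-helix prediction and mutation localization.

A Kyte-Doolittle sliding-window profile (window 19, threshold 1.6,
minimum run 15 — the classical parameters) turns a protein sequence
into an ordered set of membrane-spanning helices with alternating
sidedness starting from a cytoplasmic N-terminus, the usual orientation
for APC-superfamily transporters.  Localization maps any residue — or a
truncation point — onto this architecture: inside helix N, in the loop
between helices N and N+1 (with its side), or N-/C-terminal of the
helix bundle; truncations additionally report the helices they remove.
Helix intervals may also be supplied directly, decoupling localization
from the predictor.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

# Kyte & Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MIN_RUN = 15
MAX_HELIX_LENGTH = 30


@dataclass
class TopologyModel:
    """Ordered, non-overlapping TM helices (1-based residue intervals)."""

    helices: list[tuple[int, int]]
    n_terminus_side: str = "cytoplasmic"

    def __post_init__(self) -> None:
        last = 0
        for s, e in self.helices:
            if s <= last:
                raise ValueError("helices must be ascending and non-overlapping")
            last = e

    @property
    def n_helices(self) -> int:
        return len(self.helices)

    def _other(self) -> str:
        return "extracellular" if self.n_terminus_side == "cytoplasmic" else "cytoplasmic"

    def loop_side(self, after_helix: int) -> str:
        """Side of the loop following helix ``after_helix`` (0 = N-terminal region)."""
        return self.n_terminus_side if after_helix % 2 == 0 else self._other()

    def helix_containing(self, residue: int) -> int | None:
        for i, (s, e) in enumerate(self.helices, start=1):
            if s <= residue <= e:
                return i
        return None

    def loop_after(self, residue: int) -> int | None:
        """Index of the helix preceding the loop containing ``residue`` (0 for N-terminal)."""
        if self.helix_containing(residue) is not None:
            return None
        n = 0
        for i, (s, e) in enumerate(self.helices, start=1):
            if residue > e:
                n = i
        return n


@dataclass(frozen=True)
class Localization:
    descriptor: str
    kind: str  # helix | loop | n_terminal | c_terminal
    helix: int | None  # helix index, or the helix preceding the loop
    side: str | None
    removed_helices: tuple[int, ...] = ()

    @property
    def n_removed(self) -> int:
        return len(self.removed_helices)


def hydropathy_profile(protein: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered moving-average Kyte-Doolittle profile; ends use a shrunken window."""
    if window < 7 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 7, got {window}")
    for i, aa in enumerate(protein):
        if aa not in KYTE_DOOLITTLE:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
    values = np.array([KYTE_DOOLITTLE[aa] for aa in protein])
    n = len(values)
    half = window // 2
    cums = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (cums[hi] - cums[lo]) / (hi - lo)


def _split_long_runs(
    profile: np.ndarray, start: int, end: int, min_run: int, out: list[tuple[int, int]]
) -> None:
    """Recursively split a 0-based half-open run longer than MAX_HELIX_LENGTH
    at its internal hydropathy minimum (the minimum residue joins neither half)."""
    length = end - start
    if length < min_run:
        return
    if length <= MAX_HELIX_LENGTH:
        out.append((start, end))
        return
    inner = profile[start + min_run : end - min_run]
    m = start + min_run + int(np.argmin(inner))
    _split_long_runs(profile, start, m, min_run, out)
    _split_long_runs(profile, m + 1, end, min_run, out)


def predict_helices(
    profile: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
    n_terminus_side: str = "cytoplasmic",
) -> TopologyModel:
    """Maximal above-threshold runs of length >= min_run become TM helices."""
    if len(profile) == 0:
        raise ValueError("empty hydropathy profile")
    above = profile >= threshold
    helices: list[tuple[int, int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs: list[tuple[int, int]] = []
            _split_long_runs(profile, i, j, min_run, runs)
            helices.extend((s + 1, e) for s, e in runs)
            i = j
        else:
            i += 1
    return TopologyModel(helices=helices, n_terminus_side=n_terminus_side)


def _residue_localization(residue: int, topo: TopologyModel) -> Localization:
    if not topo.helices:
        return Localization("outside any TM helix", "loop", None, topo.n_terminus_side)
    h = topo.helix_containing(residue)
    if h is not None:
        return Localization(f"in TM helix {h}", "helix", h, None)
    k = topo.loop_after(residue)
    side = topo.loop_side(k)
    if k == 0:
        return Localization(f"N-terminal of helix 1 ({side})", "n_terminal", 0, side)
    if k == topo.n_helices:
        return Localization(
            f"C-terminal of helix {k} ({side})", "c_terminal", k, side
        )
    return Localization(
        f"in loop between TM helix {k} and {k + 1} ({side})", "loop", k, side
    )


def localize(call, topo: TopologyModel) -> Localization:
    """Localize a consequence call (or a bare residue index) on the topology.

    For truncations, the truncation point is localized and the helices
    that start beyond it are reported as removed.  A truncation point in
    the first half of a loop is described as "after TM helix N" (it has
    just cleared that helix); one in the second half as "between TM
    helix N and N+1".
    """
    truncation = getattr(call, "truncation_after", None)
    if truncation is None:
        residue = call if isinstance(call, int) else call.codon_index
        if residue is None:
            raise ValueError("call has neither a codon index nor a truncation point")
        return _residue_localization(residue, topo)

    point = truncation
    removed = tuple(
        i for i, (s, _e) in enumerate(topo.helices, start=1) if s > point
    )
    h = topo.helix_containing(point)
    if h is not None:
        return Localization(f"in TM helix {h}", "helix", h, None, removed)
    k = topo.loop_after(point)
    side = topo.loop_side(k)
    if k == 0:
        return Localization(f"N-terminal of helix 1 ({side})", "n_terminal", 0, side, removed)
    if k == topo.n_helices:
        return Localization(f"C-terminal of helix {k} ({side})", "c_terminal", k, side, removed)
    prev_end = topo.helices[k - 1][1]
    next_start = topo.helices[k][0]
    if point <= (prev_end + next_start) / 2:
        return Localization(f"after TM helix {k}", "loop", k, side, removed)
    return Localization(f"between TM helix {k} and {k + 1}", "loop", k, side, removed)
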
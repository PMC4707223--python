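"""Backbone/side-chain residue-interaction decomposition of coordination.

Every selected atom pair whose distance falls in the analysis window
contributes its per-atom coordination share ``2 / N`` to exactly one
interaction group.  A group is the unordered pair of (residue index, role)
labels of the two atoms, written compactly as e.g. ``"2B6S"`` — backbone
atoms of residue 2 against side-chain atoms of residue 6.  Group sums
therefore partition the window coordination of the same selector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .errors import DegenerateDeviationError, EmptySelectionError
from .paircorr import canonical_selector, parse_selector
from .structure_io import StructureModel

_ROLE_LETTER = {"backbone": "B", "sidechain": "S"}


def group_key(res_a: int, role_a: str, res_b: int, role_b: str) -> str:
    """Canonical unordered group label, e.g. ``group_key(6,'S',2,'B') == '2B6S'``."""
    a = (int(res_a), _ROLE_LETTER.get(role_a, role_a))
    b = (int(res_b), _ROLE_LETTER.get(role_b, role_b))
    a, b = sorted((a, b))
    return f"{a[0]}{a[1]}{b[0]}{b[1]}"


@dataclass
class InteractionGroupTable:
    window: tuple[float, float]
    selector: str
    entries: dict[str, float] = field(default_factory=dict)
    n_atoms: int = 0
    label: str = ""

    @property
    def total(self) -> float:
        return float(sum(self.entries.values()))


@dataclass
class ContributionReport:
    variant_label: str
    index_label: str
    selector: str
    window: tuple[float, float]
    substituted_residue: int
    focus_groups: tuple[str, ...]
    percent_contribution: float  # signed ratio of sums
    percent_contribution_abs: float  # ratio of absolute-value sums
    total_deviation: float
    cancellation_flag: bool  # True when |signed percent| exceeds 100


def group_coordination(
    s: StructureModel,
    selector: str = "C-C",
    window: tuple[float, float] = (5.0, 7.0),
) -> InteractionGroupTable:
    """Coordination sums R(r)dr per residue-role interaction group.

    Pairs are restricted to the species ``selector`` and to distances in
    ``[window[0], window[1])``; each pair adds ``2/N`` (its coordination
    share) to its group.
    """
    r1, r2 = window
    if not (0.0 <= r1 < r2):
        raise ValueError(f"bad window {window}")
    n = s.n_atoms
    if n < 2:
        raise EmptySelectionError("need at least 2 atoms")
    pair = parse_selector(selector)
    elements = np.char.upper(s.elements.astype("U2"))
    iu, ju = np.triu_indices(n, k=1)
    d = pdist(s.coords)
    mask = (d >= r1) & (d < r2)
    if pair is not None:
        a, b = pair
        ei, ej = elements[iu], elements[ju]
        mask &= ((ei == a) & (ej == b)) | ((ei == b) & (ej == a))
    share = 2.0 / n
    entries: dict[str, float] = {}
    for i, j in zip(iu[mask], ju[mask]):
        key = group_key(
            s.residue_indices[i], s.roles[i], s.residue_indices[j], s.roles[j]
        )
        entries[key] = entries.get(key, 0.0) + share
    return InteractionGroupTable(
        window=(float(r1), float(r2)),
        selector=canonical_selector(selector),
        entries=entries,
        n_atoms=n,
        label=s.label,
    )


def _focus_keys(keys, residue: int) -> tuple[str, ...]:
    out = []
    for k in keys:
        # keys look like '2B6S'; split into the two (res, role) halves
        halves = _split_key(k)
        if (residue, "S") in halves:
            out.append(k)
    return tuple(sorted(out))


def _split_key(key: str) -> list[tuple[int, str]]:
    halves = []
    num = ""
    for ch in key:
        if ch.isdigit():
            num += ch
        else:
            halves.append((int(num), ch))
            num = ""
    return halves


def contribution_percent(
    variant_table: InteractionGroupTable,
    index_table: InteractionGroupTable,
    substituted_residue: int,
    zero_tolerance: float = 1e-12,
) -> ContributionReport:
    """Share of the variant-vs-index coordination deviation carried by
    interaction groups involving the substituted residue's side chain.

    Groups are matched by key with missing entries treated as zero.  The
    signed percent may exceed 100 in magnitude when other groups partially
    cancel; the absolute-value variant is reported alongside.
    """
    if variant_table.selector != index_table.selector:
        raise ValueError("selector mismatch between tables")
    if variant_table.window != index_table.window:
        raise ValueError("window mismatch between tables")
    keys = set(variant_table.entries) | set(index_table.entries)
    diffs = {
        k: variant_table.entries.get(k, 0.0) - index_table.entries.get(k, 0.0)
        for k in keys
    }
    total = sum(diffs.values())
    if abs(total) < zero_tolerance:
        raise DegenerateDeviationError(
            "total coordination deviation is zero; percentage undefined"
        )
    focus = _focus_keys(keys, substituted_residue)
    focus_sum = sum(diffs[k] for k in focus)
    percent = 100.0 * focus_sum / total
    total_abs = sum(abs(v) for v in diffs.values())
    percent_abs = 100.0 * sum(abs(diffs[k]) for k in focus) / total_abs
    return ContributionReport(
        variant_label=variant_table.label,
        index_label=index_table.label,
        selector=variant_table.selector,
        window=variant_table.window,
        substituted_residue=substituted_residue,
        focus_groups=focus,
        percent_contribution=float(percent),
        percent_contribution_abs=float(percent_abs),
        total_deviation=float(total),
        cancellation_flag=abs(percent) > 100.0,
    )
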
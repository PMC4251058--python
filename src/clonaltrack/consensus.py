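"""Set-based consensus across variant callers.

A variant enters the consensus set when enough independent callers report it.
The supported rules, from strictest to loosest, are intersection (all
callers), k-of-n (explicit threshold), majority (more than half), and union
(any caller).  SNVs and indels are usually combined under different rules
because the two variant classes are typically covered by different caller
panels (three SNV callers versus two indel callers is a common design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError
from .variant_io import CallerRecord, VariantKey

RULES = ("intersection", "majority", "union", "k_of_n")


@dataclass(frozen=True)
class ConsensusRule:
    """A support threshold over n callers.

    ``name`` is one of :data:`RULES`; ``k`` is required for ``k_of_n`` and
    ignored otherwise.
    """

    name: str
    k: int | None = None

    def __post_init__(self) -> None:
        if self.name not in RULES:
            raise ConfigurationError(f"unknown consensus rule {self.name!r}; one of {RULES}")
        if self.name == "k_of_n" and (self.k is None or self.k < 1):
            raise ConfigurationError("k_of_n rule requires k >= 1")

    def min_support(self, n_callers: int) -> int:
        """Minimum number of supporting callers for emission."""
        if self.name == "intersection":
            return n_callers
        if self.name == "union":
            return 1
        if self.name == "majority":
            return n_callers // 2 + 1  # strict majority: 2 of 3, 3 of 4
        assert self.k is not None
        if self.k > n_callers:
            raise ConfigurationError(f"k={self.k} exceeds number of callers ({n_callers})")
        return self.k

    @classmethod
    def parse(cls, spec: str) -> "ConsensusRule":
        """Parse ``"majority"``, ``"intersection"``, ``"union"`` or ``"2-of-3"``/``"k=2"``."""
        s = spec.strip().lower()
        if s in ("intersection", "majority", "union"):
            return cls(s)
        if s.startswith("k="):
            return cls("k_of_n", int(s[2:]))
        if "-of-" in s:
            return cls("k_of_n", int(s.split("-of-")[0]))
        raise ConfigurationError(f"cannot parse consensus rule {spec!r}")


@dataclass(frozen=True)
class ConsensusVariant:
    """A variant emitted by the consensus rule, with all per-caller evidence.

    ``evidence`` is the single caller record designated to supply TRV/TRR
    (and hence VAF and DP) downstream.
    """

    key: VariantKey
    supporting_callers: frozenset[str]
    records: tuple[CallerRecord, ...]
    evidence: CallerRecord
    is_indel: bool = False

    def __post_init__(self) -> None:
        if not self.supporting_callers:
            raise ConfigurationError(f"consensus variant {self.key} has no supporting callers")
        if self.evidence.caller_id not in self.supporting_callers:
            raise ConfigurationError(
                f"evidence caller {self.evidence.caller_id!r} not among supporters of {self.key}"
            )


def select_evidence_record(
    records: Sequence[CallerRecord], priority: Sequence[str]
) -> CallerRecord:
    """Pick the record of the highest-priority caller present.

    Deterministic: ties cannot arise because each caller contributes at most
    one record per key.
    """
    if not records:
        raise ConfigurationError("no records to select evidence from")
    present = {r.caller_id: r for r in records}
    missing = set(present) - set(priority)
    if missing:
        raise ConfigurationError(f"caller priority {list(priority)} does not cover {sorted(missing)}")
    for caller in priority:
        if caller in present:
            return present[caller]
    raise ConfigurationError("unreachable: priority covered all callers")  # pragma: no cover


def build_consensus(
    caller_sets: Mapping[str, Iterable[CallerRecord]],
    rule: ConsensusRule | str = "majority",
    priority: Sequence[str] | None = None,
) -> list[ConsensusVariant]:
    """Combine per-caller record lists into a consensus variant list.

    Records are grouped by normalized :class:`VariantKey`; a key is emitted
    iff the number of distinct callers reporting it meets the rule's
    threshold.  The evidence record is chosen by caller ``priority``
    (default: the order callers appear in ``caller_sets``).  Output is
    sorted in karyotype order, then position.
    """
    if not caller_sets:
        raise ConfigurationError("caller_sets is empty")
    if isinstance(rule, str):
        rule = ConsensusRule.parse(rule)
    callers = list(caller_sets)
    priority = list(priority) if priority is not None else callers
    need = rule.min_support(len(callers))

    by_key: dict[VariantKey, dict[str, CallerRecord]] = {}
    for caller, records in caller_sets.items():
        for rec in records:
            slot = by_key.setdefault(rec.key, {})
            # a caller reporting the same key twice keeps its deeper record
            if caller not in slot or rec.depth > slot[caller].depth:
                slot[caller] = rec

    out: list[ConsensusVariant] = []
    for key in sorted(by_key, key=VariantKey.sort_key):
        per_caller = by_key[key]
        if len(per_caller) < need:
            continue
        records = tuple(per_caller[c] for c in callers if c in per_caller)
        evidence = select_evidence_record(records, priority)
        out.append(
            ConsensusVariant(
                key=key,
                supporting_callers=frozenset(per_caller),
                records=records,
                evidence=evidence,
                is_indel=key.is_indel,
            )
        )
    return out


def split_snv_indel(
    records: Iterable[CallerRecord],
) -> tuple[list[CallerRecord], list[CallerRecord]]:
    """Partition records into (SNVs+MNVs, indels) for per-class consensus rules."""
    snvs, indels = [], []
    for r in records:
        (indels if r.is_indel else snvs).append(r)
    return snvs, indels
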
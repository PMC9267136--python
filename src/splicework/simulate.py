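"""Synthetic carrier / control samples for the characterization pipeline.

Reads are drawn as whole transcript-species observations (multinomial over
species), not positional short reads: each simulated molecule carries its
full junction chain and, for full-length species, the allele at the variant
position.  That is exactly the information content the downstream modules
consume (junction tables, allele-tagged read records), so every upstream
operation is testable without patient data.

NMD is modeled as a per-event multiplicative detection factor in (0, 1]
applied to the event's molecular fraction before renormalization — an
observation model, not a decay mechanism.  Default 1.0 (off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import SpliceEvent
from .junctions import (
    JunctionKey,
    JunctionTable,
    ReadRecord,
    event_junctions,
    replaced_introns,
    write_sj_tab,
)
from .transcript import TranscriptModel

__all__ = [
    "SimulationSpec",
    "SimulatedSample",
    "simulate_sample",
    "simulate_control_cohort",
    "write_sj_tab",
]


@dataclass
class SimulationSpec:
    """Study conditions for one simulated carrier sample.

    ``events`` pairs each aberrant species with its true molecular fraction
    of total transcript output; ``alt_fulllength_fraction`` is the fraction
    of total output that is full-length from the variant allele (0 for a
    complete splicing defect); the remainder is wild-type full-length.
    """

    model: TranscriptModel
    events: list[tuple[SpliceEvent, float]] = field(default_factory=list)
    nmd_factor: dict[int, float] | float = 1.0
    alt_fulllength_fraction: float = 0.0
    depth: int = 5000
    control_event_fractions: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        total = 0.0
        for i, (ev, frac) in enumerate(self.events):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"event {i}: fraction {frac} outside [0, 1]")
            total += frac
            f = self._nmd(i)
            if not 0.0 < f <= 1.0:
                raise ValueError(f"event {i}: nmd factor {f} outside (0, 1]")
        if not 0.0 <= self.alt_fulllength_fraction <= 1.0:
            raise ValueError("alt_fulllength_fraction outside [0, 1]")
        if total + self.alt_fulllength_fraction > 1.0 + 1e-9:
            raise ValueError(
                "event fractions plus alt full-length fraction exceed 1"
            )
        for i, frac in self.control_event_fractions.items():
            if not 0 <= i < len(self.events):
                raise ValueError(f"control fraction for unknown event index {i}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"control fraction {frac} outside [0, 1]")

    def _nmd(self, i: int) -> float:
        if isinstance(self.nmd_factor, dict):
            return self.nmd_factor.get(i, 1.0)
        return float(self.nmd_factor)


@dataclass
class SimulatedSample:
    table: JunctionTable
    reads: list[ReadRecord]
    truth: dict[str, dict]


def _species(
    spec: SimulationSpec, fractions: list[float]
) -> list[tuple[str, float, tuple[JunctionKey, ...], str | None]]:
    """(label, probability, junction chain, allele) per transcript species.

    An aberrant molecule's chain is the annotated chain with the replaced
    intron junction(s) swapped for the event's novel junction(s).  Aberrant
    reads do not report an allele (the variant base is intronic, removed,
    or simply uninformative on that molecule class).
    """
    model = spec.model
    annotated = model.annotated_junctions()
    out = []
    weights = []
    for i, (ev, _) in enumerate(spec.events):
        novel = ev.junctions or event_junctions(ev, model)
        dropped = set(replaced_introns(ev, model, junctions=tuple(novel)))
        chain = tuple(k for k in annotated if k not in dropped) + tuple(novel)
        chain = tuple(sorted(chain, key=lambda k: (k[1], k[2])))
        w = fractions[i] * spec._nmd(i)
        out.append((ev.symbol or f"event{i}", w, chain, None))
        weights.append(w)
    aberrant_total = sum(fractions)
    alt_fl = spec.alt_fulllength_fraction
    ref_fl = max(0.0, 1.0 - aberrant_total - alt_fl)
    out.append(("fulllength_alt", alt_fl, annotated, "alt"))
    out.append(("fulllength_ref", ref_fl, annotated, "ref"))
    total_w = sum(w for _, w, _, _ in out)
    if total_w <= 0:
        raise ValueError("all species have zero probability")
    return [(lab, w / total_w, chain, allele) for lab, w, chain, allele in out]


def simulate_sample(
    spec: SimulationSpec,
    with_reads: bool = True,
    fractions: list[float] | None = None,
    seed: int | None = None,
) -> SimulatedSample:
    """Draw one sample: junction table, read records and the truth table.

    ``fractions``/``seed`` override the spec's event fractions and seed
    (used internally for control samples).  Fully deterministic for a given
    spec and seed.
    """
    spec.validate()
    if fractions is None:
        fractions = [f for _, f in spec.events]
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    species = _species(spec, fractions)
    probs = np.array([p for _, p, _, _ in species])
    counts = rng.multinomial(spec.depth, probs)

    table = JunctionTable(f"sim-{spec.model.transcript_id}")
    for (label, _, chain, _), n in zip(species, counts):
        if n == 0:
            continue
        for key in chain:
            table.add(key, int(n))

    reads: list[ReadRecord] = []
    if with_reads:
        ridx = 0
        for (label, _, chain, allele), n in zip(species, counts):
            for _ in range(int(n)):
                reads.append(ReadRecord(f"r{ridx:07d}", chain, allele))
                ridx += 1

    truth = {
        label: {
            "probability": float(p),
            "count": int(n),
            "realized_fraction": float(n) / spec.depth,
        }
        for (label, p, _, _), n in zip(species, counts)
    }
    return SimulatedSample(table, reads, truth)


def simulate_control_cohort(
    spec: SimulationSpec, n_controls: int = 5
) -> list[JunctionTable]:
    """Simulate control samples sharing the carrier's transcript model.

    Events appear only at their background (``control_event_fractions``)
    levels — e.g. a naturally occurring alternative splicing event at a
    fraction of a percent.  Controls carry no variant allele.  Per-control
    seeds derive from the spec seed, so the cohort is reproducible.
    """
    if n_controls < 1:
        raise ValueError("need at least one control")
    spec.validate()
    bg = [
        spec.control_event_fractions.get(i, 0.0)
        for i in range(len(spec.events))
    ]
    tables = []
    for c in range(n_controls):
        sub_seed = (spec.seed * 1_000_003 + 7919 * (c + 1)) % (2**31 - 1)
        sample = simulate_sample(
            _control_spec(spec), with_reads=False, fractions=bg, seed=sub_seed
        )
        sample.table.sample_id = f"control-{c + 1}"
        tables.append(sample.table)
    return tables


def _control_spec(spec: SimulationSpec) -> SimulationSpec:
    return SimulationSpec(
        model=spec.model,
        events=spec.events,
        nmd_factor=spec.nmd_factor,
        alt_fulllength_fraction=0.0,
        depth=spec.depth,
        control_event_fractions=spec.control_event_fractions,
        seed=spec.seed,
    )
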
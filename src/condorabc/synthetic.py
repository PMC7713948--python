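"""Synthetic datasets emulating the condor mtDNA study design.

The default fixture mirrors the structure of the empirical data: 73 samples
(35 historical, 1884-1946; 38 contemporary, 1961-2013) over three regions
(north 24 / central 28 / south 21), collapsing to six haplotypes on a 310 bp
alignment (145 bp Control region + 165 bp 12S).  Four haplotypes occur in the
historical stratum (one of them only there, carrying two Control-region
transitions) and five in the contemporary stratum, so one matriline is lost
between periods (1/6 = 17%).  Sequences are synthetic: structurally, not
numerically, faithful to any real accession.

Pseudo-observed datasets (pods) for ABC validation are drawn through the
coalescent simulator with their true generating parameters attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .abc import PriorConfig, draw_prior
from .coalsim import (MutationModel, SamplingDesign, ScenarioParams,
                      condor_design, condor_mutation_model, simulate_dataset)
from .samples import (CONTEMPORARY, DEFAULT_PARTITIONS, HISTORICAL,
                      SampleRecord, SampleSet, write_samples)

_REGION_CENTERS = {
    "north": (2.0, -76.0),
    "central": (-24.0, -66.0),
    "south": (-41.0, -71.0),
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class HaplotypeSpec:
    """One designed haplotype: transitions applied to the reference at the
    given 0-based alignment positions, plus counts per (period, region)."""

    name: str
    edit_positions: tuple[int, ...]
    counts: dict[tuple[str, str], int]


@dataclass(frozen=True)
class FixtureSpec:
    n_historical: int = 35
    n_contemporary: int = 38
    historical_years: tuple[int, int] = (1884, 1946)
    contemporary_years: tuple[int, int] = (1961, 2013)
    length: int = 310
    blueprint: tuple[HaplotypeSpec, ...] = ()

    def validate(self) -> None:
        for per, n in ((HISTORICAL, self.n_historical),
                       (CONTEMPORARY, self.n_contemporary)):
            tot = sum(c for h in self.blueprint
                      for (p, _), c in h.counts.items() if p == per)
            if tot != n:
                raise ValueError(
                    f"blueprint {per} counts sum to {tot}, expected {n}")
        for h in self.blueprint:
            if any(not 0 <= p < self.length for p in h.edit_positions):
                raise ValueError(f"{h.name}: edit position outside alignment")


def default_fixture_spec() -> FixtureSpec:
    """Six-haplotype blueprint with strong north vs central-south sorting.

    H6 is the historical-only lineage: two Control-region transitions,
    echoing the empirically reported private coastal matriline.  H3 occurs
    only in the north and only in the contemporary stratum; H4 and H5 only
    in the south.
    """
    blueprint = (
        HaplotypeSpec("H1", (), {
            (HISTORICAL, "north"): 12, (HISTORICAL, "central"): 8,
            (HISTORICAL, "south"): 2, (CONTEMPORARY, "north"): 8,
            (CONTEMPORARY, "central"): 4,
        }),
        HaplotypeSpec("H2", (200,), {
            (HISTORICAL, "central"): 6, (HISTORICAL, "south"): 4,
            (CONTEMPORARY, "central"): 10, (CONTEMPORARY, "south"): 8,
        }),
        HaplotypeSpec("H3", (50,), {(CONTEMPORARY, "north"): 4}),
        HaplotypeSpec("H4", (200, 210), {(CONTEMPORARY, "south"): 2}),
        HaplotypeSpec("H5", (220,), {
            (HISTORICAL, "south"): 2, (CONTEMPORARY, "south"): 2,
        }),
        HaplotypeSpec("H6", (30, 60), {(HISTORICAL, "south"): 1}),
    )
    return FixtureSpec(blueprint=blueprint)


def make_condor_like_fixture(spec: FixtureSpec | None = None, seed: int = 0,
                             out_dir: str | Path | None = None) -> SampleSet:
    """Deterministic condor-like SampleSet (optionally written to
    FASTA + CSV under ``out_dir``)."""
    spec = spec or default_fixture_spec()
    spec.validate()
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list("ACGT"), p=[0.30, 0.30, 0.15, 0.25])
                  for _ in range(spec.length))
    hap_seqs = {}
    for h in spec.blueprint:
        s = list(ref)
        for pos in h.edit_positions:
            s[pos] = _TRANSITION[s[pos]]
        hap_seqs[h.name] = "".join(s)
    if len(set(hap_seqs.values())) != len(hap_seqs):
        raise ValueError("blueprint edits do not yield distinct haplotypes")

    year_ranges = {HISTORICAL: spec.historical_years,
                   CONTEMPORARY: spec.contemporary_years}
    records = []
    i = 0
    for h in spec.blueprint:
        for (period, region), count in sorted(h.counts.items()):
            lo, hi = year_ranges[period]
            lat0, lon0 = _REGION_CENTERS.get(region, (0.0, 0.0))
            for _ in range(count):
                records.append(SampleRecord(
                    sample_id=f"VG{i:03d}",
                    year=int(rng.integers(lo, hi + 1)),
                    latitude=round(lat0 + rng.uniform(-3, 3), 4),
                    longitude=round(lon0 + rng.uniform(-3, 3), 4),
                    region=region,
                    sequence=hap_seqs[h.name],
                    period=period,
                ))
                i += 1
    sample_set = SampleSet(records, DEFAULT_PARTITIONS)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_samples(sample_set, out / "sequences.fasta", out / "metadata.csv")
    return sample_set


def generate_pods(scenario_id: int, prior_or_params, n_pods: int,
                  design: SamplingDesign | None = None,
                  model: MutationModel | None = None,
                  seed=None) -> list[tuple[SampleSet, ScenarioParams]]:
    """Pseudo-observed datasets with their true generating parameters.

    ``prior_or_params`` is either a PriorConfig (each pod draws fresh
    parameters) or a fixed ScenarioParams shared by all pods."""
    design = design or condor_design()
    model = model or condor_mutation_model()
    rng = np.random.default_rng(seed)
    pods = []
    for _ in range(n_pods):
        if isinstance(prior_or_params, PriorConfig):
            sp = draw_prior(scenario_id, prior_or_params, rng)
        elif isinstance(prior_or_params, ScenarioParams):
            sp = prior_or_params
        else:
            raise TypeError("expected PriorConfig or ScenarioParams")
        ds = simulate_dataset(sp, model, design, seed=rng.integers(2**31))
        pods.append((ds, sp))
    return pods
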
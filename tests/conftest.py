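"""Shared fixtures: a session-scoped seeded simulation and small builders."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from yeastsplice import (
    FilterConfig,
    GenomicInterval,
    PredictedIntron,
    SimulationConfig,
    call_potential_introns,
    extract_split_reads,
    filter_potential_introns,
    read_annotation,
    read_genome,
    simulate_dataset,
    valid_signal_set,
)

SAM_HEADER = "@HD\tVN:1.6\n"


def write_sam(path, chrom_lengths: dict[str, int], records: list[str]) -> str:
    """Minimal SAM writer for handcrafted alignment fixtures."""
    lines = [SAM_HEADER.rstrip("\n")]
    for name, length in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.extend(records)
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def sam_record(
    name: str,
    chrom: str,
    pos: int,
    cigar: str,
    flag: int = 0,
    nh: int | None = 1,
    seq: str = "*",
) -> str:
    fields = [name, str(flag), chrom, str(pos), "60", cigar, "*", "0", "0", seq, "*"]
    if nh is not None:
        fields.append(f"NH:i:{nh}")
    return "\t".join(fields)


def make_predicted(
    chrom="chrI",
    start=101,
    end=200,
    strand="+",
    support=10,
    fragments=None,
    anchors=(90, 90),
    slack=0,
) -> PredictedIntron:
    return PredictedIntron(
        interval=GenomicInterval(chrom, start, end, strand),
        read_support=support,
        fragment_support=fragments if fragments is not None else support,
        anchor_left=anchors[0],
        anchor_right=anchors[1],
        donor="GT",
        acceptor="AG",
        slack=slack,
        score_left=anchors[0] - slack,
        score_right=anchors[1] - slack,
    )


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """Default-conditions simulation with all event kinds, loaded back through
    the package's own readers."""
    out = tmp_path_factory.mktemp("sim")
    config = SimulationConfig(seed=11, n_genes=50)
    paths, truth = simulate_dataset(config, out)
    genome = read_genome(paths["fasta"])
    annotation = read_annotation(paths["gff"], genome)
    return SimpleNamespace(
        config=config,
        paths=paths,
        truth=truth,
        genome=genome,
        annotation=annotation,
    )


@pytest.fixture(scope="session")
def sim_predicted(sim):
    """Predicted introns from running the full cascade on the simulation."""
    potential = call_potential_introns(extract_split_reads(sim.paths["sam"]))
    signals = valid_signal_set(sim.annotation, sim.genome)
    config = FilterConfig(valid_signals=signals)
    predicted, tally = filter_potential_introns(potential, sim.genome, config)
    return SimpleNamespace(
        potential=potential, predicted=predicted, tally=tally, filter_config=config
    )
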
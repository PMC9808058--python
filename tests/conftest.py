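from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from repsig import (
    GeneAnnotation,
    RepeatFeature,
    RepeatomeSimConfig,
    SurvivalData,
    build_matrix,
    generate_repeat_landscape,
)


@pytest.fixture
def toy_genes() -> list[GeneAnnotation]:
    return [
        GeneAnnotation("gA", "chr1", "+", tss=10000, start=10000, end=11000),
        GeneAnnotation("gB", "chr1", "-", tss=29999, start=29000, end=30000),
        GeneAnnotation("gC", "chr2", "+", tss=5000, start=5000, end=6000),
    ]


@pytest.fixture
def toy_repeats() -> list[RepeatFeature]:
    return [
        RepeatFeature("chr1", 8200, 8500, "AluY", "SINE/Alu"),       # inside gA promoter
        RepeatFeature("chr1", 7900, 8100, "AluSx", "SINE/Alu"),      # clipped at gA promoter start
        RepeatFeature("chr1", 9500, 9600, "L1HS", "LINE/L1"),        # inside gA promoter
        RepeatFeature("chr1", 30500, 30800, "L1PA2", "LINE/L1"),     # inside gB promoter (- strand)
        RepeatFeature("chr1", 50000, 50300, "AluJb", "SINE/Alu"),    # far from any promoter
        RepeatFeature("chr2", 4000, 4200, "MIRb", "SINE/MIR"),       # inside gC promoter
    ]


def random_gene_repeat_config(rng: np.random.Generator):
    """One randomized toy configuration for oracle-equivalence checks."""
    window = int(rng.integers(500, 3000))
    contigs = [f"c{k}" for k in range(int(rng.integers(1, 3)))]
    classes = ["SINE/Alu", "LINE/L1", "SINE/MIR"][: int(rng.integers(1, 4))]
    genes = []
    for i in range(int(rng.integers(3, 9))):
        start = int(rng.integers(window, 50_000))
        end = start + int(rng.integers(200, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(
            gene_id=f"g{i}", contig=str(rng.choice(contigs)), strand=strand,
            tss=start if strand == "+" else end - 1, start=start, end=end))
    repeats = []
    for j in range(int(rng.integers(20, 60))):
        start = int(rng.integers(0, 55_000))
        repeats.append(RepeatFeature(
            contig=str(rng.choice(contigs)), start=start,
            end=start + int(rng.integers(1, 1200)),
            repeat_name=f"r{j}", repeat_class=str(rng.choice(classes))))
    return genes, repeats, window


@pytest.fixture(scope="session")
def default_landscape():
    """Default planted landscape (seed 0) with its RC matrix, shared read-only."""
    config = RepeatomeSimConfig(seed=0)
    genes, repeats, truth = generate_repeat_landscape(config)
    matrix = build_matrix(genes, repeats, window_bp=config.window_bp)
    return config, genes, repeats, truth, matrix


@pytest.fixture
def toy_survival() -> SurvivalData:
    frame = pd.DataFrame(
        {"time": [1.0, 3.0, 2.0, 4.0], "event": [1, 1, 0, 0]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"))
    return SurvivalData(frame)
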
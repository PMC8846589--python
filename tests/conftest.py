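import json
from pathlib import Path

import pytest

from regulonkit.cli import run_all
from regulonkit.synthetic_data import SimConfig, simulate_study

# printed EMSA probe sequences (50-mers), with and without the core motif
PROBE_WITH_MOTIF = "AAACAAAGATTCTAAGCATCCATTATTAATATACATCCCTAGAAAAAATC"
PROBE_WITHOUT_MOTIF = "ATCGAAAACAAAGATTCTAAGCATCATACATCCCTAGAAAAAATCTCCGC"


@pytest.fixture(scope="session")
def sim_study(tmp_path_factory):
    """One default synthetic study (seed 1) shared across tests."""
    out = tmp_path_factory.mktemp("sim_default")
    truth = simulate_study(SimConfig(seed=1), out)
    return out, truth


@pytest.fixture(scope="session")
def pipeline_run(sim_study, tmp_path_factory):
    """Full pipeline executed on the shared synthetic study."""
    sim_dir, truth = sim_study
    out = tmp_path_factory.mktemp("pipeline_default")
    manifest = run_all(
        sorted(sim_dir.glob("rep*.narrowPeak")),
        sim_dir / "genes.gff3",
        sim_dir / "genome.fa",
        sim_dir / "de.tsv",
        sim_dir / "metacells.tsv",
        out,
        tf_gene_id=truth.tf_gene_id,
    )
    return out, truth, manifest
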
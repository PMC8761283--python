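from pathlib import Path

import pandas as pd
import pytest

from coremut import (CorePromoter, RunConfig, default_cohort_spec,
                     generate_fixture, run_pipeline)


@pytest.fixture
def toy_promoter() -> CorePromoter:
    # 10 up + 10 down around the TSS; sequence chosen non-repetitive
    return CorePromoter(gene_id="TOY", chrom="chrT", tss=1000, strand="+",
                        window_up=10, window_down=10,
                        sequence="ACGTACGGTTCAGATCCATG")


@pytest.fixture(scope="session")
def cohort(tmp_path_factory) -> dict:
    """Default 77-case synthetic cohort, generated and analysed once."""
    root = tmp_path_factory.mktemp("cohort")
    spec = default_cohort_spec(seed=11)
    paths = generate_fixture(spec, root / "fixture")
    config = RunConfig(
        promoter_bed=str(paths["bed"]),
        reference_fasta=str(paths["fasta"]),
        vcf_dir=str(paths["vcf_dir"]),
        panel_paths=[str(paths["panel"])],
        catalog_dir=str(paths["catalog_dir"]),
        expression_matrix=str(paths["expression"]),
        expression_groups=str(paths["groups"]),
        luciferase_table=str(paths["luciferase"]),
        driver_panel=str(paths["driver_panel"]),
        out_dir=str(root / "out"),
        seed=11)
    result = run_pipeline(config)
    truth = pd.read_csv(paths["truth_mutations"], sep="\t")
    return {"spec": spec, "paths": paths, "config": config,
            "result": result, "truth": truth, "root": root}
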
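import numpy as np
import pandas as pd
import pytest

import panphen as pp


@pytest.fixture
def toy_tree():
    """Balanced 4-tip tree with unit branch lengths."""
    return pp.StrainTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def toy_means():
    return {"A": 10.0, "B": 10.0, "C": 20.0, "D": 20.0}


def pheno_from_dict(groups: dict[str, list[float]], **extra) -> pp.PhenotypeTable:
    rows = []
    for strain, vals in groups.items():
        for i, v in enumerate(vals, start=1):
            row = {"strain": strain, "replicate": f"r{i}", "offspring": v}
            for k, col in extra.items():
                row[k] = col[strain][i - 1] if isinstance(col, dict) else col
            rows.append(row)
    return pp.PhenotypeTable(pd.DataFrame(rows))


@pytest.fixture
def toy_pheno():
    """Replicate-level table whose strain means are the toy means."""
    return pheno_from_dict(
        {"A": [8, 12], "B": [10, 10], "C": [18, 22], "D": [20, 20]}
    )


@pytest.fixture(scope="session")
def paperlike(tmp_path_factory):
    """Paperlike fixture written to disk and read back through data_io."""
    outdir = tmp_path_factory.mktemp("paperlike")
    cfg = pp.paperlike_config(seed=3)
    paths = pp.make_fixture(cfg, outdir)
    truth = pd.read_csv(paths["truth"], sep="\t")
    return {
        "cfg": cfg,
        "paths": paths,
        "tree": pp.read_tree(paths["tree"]),
        "pa": pp.read_pa_matrix(paths["pa_matrix"]),
        "pheno": pp.read_phenotypes(paths["phenotypes"]),
        "truth": truth,
    }


def random_small_tree(rng: np.random.Generator, max_tips: int = 8) -> pp.StrainTree:
    n_tips = int(rng.integers(3, max_tips + 1))
    cfg = pp.SimConfig(n_strains=n_tips, seed=int(rng.integers(2**31)))
    return pp.simulate_tree(cfg)
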
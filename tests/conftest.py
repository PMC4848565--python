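import pandas as pd
import pytest

from interomap.types import ExpressionMatrix, GODag


@pytest.fixture(scope="session")
def chain_dag():
    """root <- A <- B in BP, plus MF/CC roots so all namespaces exist."""
    terms = {
        "GO:0000001": ("bp root", "BP"),
        "GO:0000002": ("A", "BP"),
        "GO:0000003": ("B", "BP"),
        "GO:0100001": ("mf root", "MF"),
        "GO:0200001": ("cc root", "CC"),
    }
    edges = [
        ("GO:0000002", "GO:0000001", "is_a"),
        ("GO:0000003", "GO:0000002", "is_a"),
    ]
    return GODag(terms, edges)


@pytest.fixture(scope="session")
def diamond_dag():
    """BP diamond: root <- L, R; B is_a both L and R.  Extra leaf under L."""
    terms = {
        "GO:0000001": ("bp root", "BP"),
        "GO:0000010": ("left", "BP"),
        "GO:0000020": ("right", "BP"),
        "GO:0000030": ("bottom", "BP"),
        "GO:0000011": ("left leaf", "BP"),
        "GO:0100001": ("mf root", "MF"),
        "GO:0200001": ("cc root", "CC"),
    }
    edges = [
        ("GO:0000010", "GO:0000001", "is_a"),
        ("GO:0000020", "GO:0000001", "is_a"),
        ("GO:0000030", "GO:0000010", "is_a"),
        ("GO:0000030", "GO:0000020", "is_a"),
        ("GO:0000011", "GO:0000010", "is_a"),
    ]
    return GODag(terms, edges)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic bundle (seed 1), generated once per session."""
    from interomap.synthetic import FixtureConfig, generate_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    config = FixtureConfig(seed=1)
    paths, truth = generate_bundle(config, outdir)
    return config, paths, truth


@pytest.fixture(scope="session")
def loaded_bundle(default_bundle):
    """The default bundle read back through the io layer."""
    from interomap.pipeline import PipelineConfig, _load_bundle

    config, paths, truth = default_bundle
    cfg = PipelineConfig(bundle_dir=str(paths.directory), output_dir=".")
    ref_ppis, omap, dag, annotations, tables, expr = _load_bundle(cfg)
    return {
        "config": config,
        "truth": truth,
        "ref_ppis": ref_ppis,
        "orthologs": omap,
        "dag": dag,
        "annotations": annotations,
        "tables": tables,
        "expr": expr,
    }


def balanced_expression(rows: dict[str, list[float]], center: float = 10.0) -> ExpressionMatrix:
    """Expression matrix whose per-sample mean is exactly ``center``.

    For every listed gene a mirror gene with values 2*center - x is added,
    pinning each column mean at ``center`` so deviation signs are exact.
    """
    data = dict(rows)
    for gene, values in rows.items():
        data[f"mirror_{gene}"] = [2 * center - v for v in values]
    n = len(next(iter(rows.values())))
    frame = pd.DataFrame(data, index=[f"s{i}" for i in range(n)]).T
    return ExpressionMatrix(frame)
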
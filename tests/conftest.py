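import numpy as np
import pytest

from modfinger.io_formats import ExpressionMatrix, Module, ModuleSet, SampleMetadata


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 samples, hand-enumerable."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [5.0, 5.5, 6.0, 6.5],
            [0.0, -1.0, 1.0, 0.5],
        ]
    )
    return ExpressionMatrix(["gA", "gB", "gC"], ["s1", "s2", "s3", "s4"], values)


@pytest.fixture
def two_group_meta() -> SampleMetadata:
    return SampleMetadata(
        ["s1", "s2", "s3", "s4"], ["case", "case", "ctrl", "ctrl"]
    )


@pytest.fixture
def small_modules() -> ModuleSet:
    return ModuleSet(
        [
            Module("M1", "alpha", ("gA", "gB")),
            Module("M2", "beta", ("gB", "gC")),
        ]
    )


def random_expression(
    rng: np.random.Generator, n_genes: int, groups: dict[str, int],
    shift_genes: int = 0, shift: float = 0.0, sd: float = 0.3, baseline: float = 8.0,
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Plain Gaussian matrix helper for oracle tests (first group shifted)."""
    labels: list[str] = []
    sample_ids: list[str] = []
    for g, n in groups.items():
        for j in range(n):
            sample_ids.append(f"{g}{j}")
            labels.append(g)
    n_samples = len(sample_ids)
    x = baseline + rng.standard_normal((n_genes, n_samples)) * sd
    first = next(iter(groups))
    cols = [j for j, l in enumerate(labels) if l == first]
    x[np.ix_(range(shift_genes), cols)] += shift
    expr = ExpressionMatrix(
        [f"g{i:04d}" for i in range(n_genes)], sample_ids, x
    )
    meta = SampleMetadata(sample_ids, labels, allowed_groups=tuple(groups))
    return expr, meta
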
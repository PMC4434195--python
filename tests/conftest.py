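import numpy as np
import pytest

from pedstrat import aims, pca, simulate


@pytest.fixture(scope="session")
def stratified():
    """Full-scale stratified dataset: 20 extended families (22-86 members),
    20,000 unlinked variants, Fst 0.2 with planted divergent family pairs."""
    cfg = simulate.SimulationConfig(seed=7, n_variants=20_000)
    return simulate.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def stratified_analysis(stratified):
    """Random-panel PCA, divergent pairs, delta AIMs and AIM-panel PCA on the
    stratified dataset (shared across tests to avoid recomputation)."""
    d = stratified
    rng = np.random.default_rng(3)
    rpanel = pca.sample_panel(d.genotypes, 10_000, 0.1, rng)
    rres = pca.run_pca(d.genotypes, rpanel, n_components=150)
    pairs = aims.find_divergent_pairs(aims.family_pc_means(rres, d.pedigree))
    panels = [
        aims.select_aims(aims.pair_frequencies(d.genotypes, d.pedigree, p), 0.6)
        for p in pairs
    ]
    merged = aims.merge_panels(panels)
    ares = pca.run_pca(d.genotypes, merged, n_components=150)
    return {
        "data": d,
        "random_pca": rres,
        "pairs": pairs,
        "panels": panels,
        "merged": merged,
        "aim_pca": ares,
    }


@pytest.fixture(scope="session")
def small_data():
    """Tiny stratified dataset for fast unit tests."""
    cfg = simulate.SimulationConfig(
        seed=11, n_families=6, family_size_range=(8, 14),
        n_variants=300, n_causal=5,
    )
    return simulate.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def shared_small():
    """Small ancestry-homogeneous dataset (no stratification)."""
    cfg = simulate.SimulationConfig(
        seed=13, n_families=12, family_size_range=(15, 25),
        n_variants=2_500, n_causal=10,
        admixture="shared", plant_divergent_pairs=False,
    )
    return simulate.simulate_dataset(cfg)
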
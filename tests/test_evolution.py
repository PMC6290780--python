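import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdssgrn.evolution import (
    EvolutionConfig,
    FitnessEvaluator,
    crossover_binary,
    crossover_chromosomes,
    crossover_real,
    crossover_structure,
    fitness,
    gamma_schedule,
    mutate_binary,
    mutate_chromosome,
    mutate_real,
    mutate_structure,
    roulette_select,
)
from tdssgrn.simulation import IntegratorConfig, TimeSeriesDataset, simulate_network
from tdssgrn.tdss_core import (
    Chromosome,
    ConfigurationError,
    ParamIntervals,
    SymbolAlphabet,
    random_chromosome,
    random_gene,
)

from conftest import make_gene


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def constant_rate_chromosome(alphabet, alpha, beta):
    """Encodes dX = alpha - beta (both genes decode to bare constants)."""
    g1 = make_gene(alphabet, ["R", "x1"], ["x1"] * 5, rate=alpha)
    g2 = make_gene(alphabet, ["R", "x1"], ["x1"] * 5, rate=beta)
    return Chromosome(g1, g2)


def test_fitness_hand_computed_sse(alphabet):
    # 1 gene, 2 time points; dX = 0.5 exactly -> prediction [1, 1.5]
    ds = TimeSeriesDataset(times=[0.0, 1.0], values=np.array([[1.0, 2.0]]))
    ab = SymbolAlphabet(arities=(2, 3), n_genes=1)
    chrom = constant_rate_chromosome(ab, 2.0, 1.5)
    cfg = EvolutionConfig(population_size=2, max_iterations=1, partitions=1,
                          function_set=(2, 3), substeps=4)
    f = fitness(chrom, 0, [ds], cfg)
    assert f == pytest.approx(1.0 / (1.0 + 0.25), rel=1e-12)


def test_fitness_true_equation_near_one(rng):
    # self-decay toward alpha/beta; the true chromosome must score ~1
    ab = SymbolAlphabet(arities=(2,), n_genes=1)
    g1 = make_gene(ab, ["R", "x1"], ["x1"] * 3, rate=1.2)
    g2 = make_gene(ab, ["x1", "x1"], ["x1"] * 3, rate=0.8,
                   kinetic=np.array([1.0, 0.0, 0.0, 0.0]))
    chrom = Chromosome(g1, g2)
    from tdssgrn.tdss_core import decode_chromosome
    eq = decode_chromosome(chrom, 0)
    ds = simulate_network([eq], np.array([2.0]), np.linspace(0, 10, 21),
                          IntegratorConfig(substeps=10))
    cfg = EvolutionConfig(population_size=2, function_set=(2,), substeps=10)
    assert fitness(chrom, 0, [ds], cfg) > 0.9999


def test_fitness_divergent_is_zero():
    ds = TimeSeriesDataset(times=np.linspace(0, 10, 11),
                           values=np.vstack([np.full(11, 2.0)]))
    ab = SymbolAlphabet(arities=(2,), n_genes=1)
    g1 = make_gene(ab, ["x1", "x1"], ["x1"] * 3, rate=3.0,
                   kinetic=np.array([5.0, 0.0, 0.0, 0.0]))
    g2 = make_gene(ab, ["R", "x1"], ["x1"] * 3, rate=0.0)
    chrom = Chromosome(g1, g2)  # dX = 3 X^5: blows up
    cfg = EvolutionConfig(population_size=2, function_set=(2,),
                          kinetic_interval=(0.0, 5.0), substeps=10)
    assert fitness(chrom, 0, [ds], cfg) == 0.0


# ---------------------------------------------------------------------------
# structure mutation
# ---------------------------------------------------------------------------

def test_single_point_tail_stays_terminal(alphabet, intervals, rng):
    g = random_gene(alphabet, 2, intervals, rng)
    for _ in range(10_000):
        m = mutate_structure(g, "single_point", rng, intervals)
        assert all(s in alphabet.terminal_symbols for s in m.tail)
        assert all(s in alphabet.all_symbols for s in m.head)


def test_all_variables_changes_terminals_keeps_shape(alphabet, intervals, rng):
    from tdssgrn.tdss_core import expressed_length
    g = make_gene(alphabet, ["*3", "x3"], ["x1", "x2", "x5", "x5", "x5"])
    m = mutate_structure(g, "all_variables", rng, intervals)
    assert m.head[0] == "*3"  # functions untouched
    assert expressed_length(m) == expressed_length(g)
    for pos in range(expressed_length(g)):
        sym = (g.head + g.tail)[pos]
        if not alphabet.is_function(sym):
            assert (m.head + m.tail)[pos] != sym


def test_single_gene_reproducible(alphabet, intervals):
    g = random_gene(alphabet, 2, intervals, np.random.default_rng(3))
    m1 = mutate_structure(g, "single_gene", np.random.default_rng(9), intervals)
    m2 = mutate_structure(g, "single_gene", np.random.default_rng(9), intervals)
    assert m1.head == m2.head and m1.tail == m2.tail
    assert m1.rate_constant == m2.rate_constant


def test_unknown_strategy_raises(alphabet, intervals, rng):
    g = random_gene(alphabet, 2, intervals, rng)
    with pytest.raises(ConfigurationError):
        mutate_structure(g, "bogus", rng, intervals)


# ---------------------------------------------------------------------------
# real mutation
# ---------------------------------------------------------------------------

def test_mutate_real_identity_at_zero_probability(rng):
    v = rng.uniform(0, 1, 50)
    out = mutate_real(v, (0, 1), 0.0, 0.1, rng)
    np.testing.assert_array_equal(out, v)


def test_mutate_real_degenerate_gaussian(rng):
    v = rng.uniform(0.2, 0.8, 50)
    out = mutate_real(v, (0, 1), 1.0, 0.0, rng)
    np.testing.assert_allclose(out, v, atol=1e-9)


def test_mutate_real_moments(rng):
    n = 100_000
    sigma = 0.1
    v = np.zeros(n)
    out = mutate_real(v, (-10, 10), 1.0, sigma, rng)  # interval wide: no clip
    d = out - v
    se_mean = sigma / np.sqrt(n)
    assert abs(d.mean()) < 3 * se_mean
    se_var = sigma ** 2 * np.sqrt(2.0 / n)
    assert abs(d.var() - sigma ** 2) < 3 * se_var


def test_mutate_real_respects_interval(rng):
    v = rng.uniform(0, 1, 1000)
    out = mutate_real(v, (0, 1), 1.0, 5.0, rng)
    assert (out >= 0).all() and (out <= 1).all()


# ---------------------------------------------------------------------------
# binary mutation
# ---------------------------------------------------------------------------

def test_mutate_binary_identity(rng):
    bits = rng.integers(0, 2, 64).astype(np.uint8)
    np.testing.assert_array_equal(mutate_binary(bits, 0.0, rng), bits)


def test_mutate_binary_full_inversion(rng):
    bits = np.array([0, 1], dtype=np.uint8)
    np.testing.assert_array_equal(mutate_binary(bits, 1.0, rng),
                                  np.array([1, 0], dtype=np.uint8))


def test_mutate_binary_flip_frequency(rng):
    n = 100_000
    p = 0.3
    bits = np.zeros(n, dtype=np.uint8)
    flipped = mutate_binary(bits, p, rng).sum()
    se = np.sqrt(p * (1 - p) * n)
    assert abs(flipped - p * n) < 3 * se


# ---------------------------------------------------------------------------
# structure crossover
# ---------------------------------------------------------------------------

def test_crossover_with_self_is_identity(alphabet, intervals, rng):
    c = random_chromosome(alphabet, 2, intervals, rng)
    for strat in ("single_point", "single_gene"):
        a, b = crossover_structure(c, c.copy(), strat, rng)
        assert a.to_text() == c.to_text()
        assert b.to_text() == c.to_text()


def test_single_gene_swap_conserves_gene_multiset(alphabet, intervals, rng):
    x = random_chromosome(alphabet, 2, intervals, rng)
    y = random_chromosome(alphabet, 2, intervals, rng)
    before = sorted(g.head + g.tail for g in (x.gene1, x.gene2, y.gene1, y.gene2))
    a, b = crossover_structure(x, y, "single_gene", rng)
    after = sorted(g.head + g.tail for g in (a.gene1, a.gene2, b.gene1, b.gene2))
    assert before == after


def test_single_point_crossover_legality(alphabet, intervals, rng):
    for _ in range(10_000):
        x = random_chromosome(alphabet, 2, intervals, rng)
        y = random_chromosome(alphabet, 2, intervals, rng)
        a, b = crossover_structure(x, y, "single_point", rng)
        for c in (a, b):
            c.gene1.validate(intervals)
            c.gene2.validate(intervals)


# ---------------------------------------------------------------------------
# real crossover + gamma schedule
# ---------------------------------------------------------------------------

def test_crossover_real_worked_example():
    xo, yo = crossover_real(np.array([1.0]), np.array([3.0]), 0.5)
    assert xo[0] == 0.0 and yo[0] == 4.0


def test_crossover_real_gamma_zero_identity(rng):
    x, y = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
    xo, yo = crossover_real(x, y, 0.0)
    np.testing.assert_array_equal(xo, x)
    np.testing.assert_array_equal(yo, y)


def test_crossover_real_sum_conserved_exact(rng):
    # the algebraic identity, checked exactly by running the production
    # operator on exact rationals
    from fractions import Fraction
    for _ in range(2_000):
        x = np.array([Fraction(v).limit_denominator(10**6)
                      for v in rng.uniform(-5, 5, 4)], dtype=object)
        y = np.array([Fraction(v).limit_denominator(10**6)
                      for v in rng.uniform(-5, 5, 4)], dtype=object)
        gamma = Fraction(rng.uniform(0, 1)).limit_denominator(10**6)
        xo, yo = crossover_real(x, y, gamma)  # no clipping
        assert all(a + b == c + d for a, b, c, d in zip(xo, yo, x, y))


def test_crossover_real_sum_conserved_float_ulp(rng):
    for _ in range(10_000):
        x = rng.uniform(-5, 5, 4)
        y = rng.uniform(-5, 5, 4)
        gamma = rng.uniform(0, 1)
        xo, yo = crossover_real(x, y, gamma)  # no clipping
        # absolute rounding error is a few ulp of the operand scale
        np.testing.assert_allclose(xo + yo, x + y, rtol=0, atol=1e-13)


def test_gamma_schedule():
    assert gamma_schedule(0, 1.0) == 1.0
    assert gamma_schedule(1, 1.0) == pytest.approx(0.99)
    assert gamma_schedule(2, 1.0) == pytest.approx(0.9801)


# ---------------------------------------------------------------------------
# binary crossover
# ---------------------------------------------------------------------------

class _FixedRNG:
    """Duck-typed rng returning fixed draws for integers()."""

    def __init__(self, *values):
        self.values = list(values)

    def integers(self, *a, **k):
        return self.values.pop(0)


def test_crossover_binary_identical_parents(rng):
    bits = rng.integers(0, 2, 16).astype(np.uint8)
    for strat in ("single_point", "two_point"):
        a, b = crossover_binary(bits, bits.copy(), strat, rng)
        np.testing.assert_array_equal(a, bits)
        np.testing.assert_array_equal(b, bits)


def test_crossover_binary_point_zero_is_identity():
    x = np.array([1, 1, 1, 1], dtype=np.uint8)
    y = np.array([0, 0, 0, 0], dtype=np.uint8)
    a, b = crossover_binary(x, y, "single_point", _FixedRNG(0))
    np.testing.assert_array_equal(a, x)
    np.testing.assert_array_equal(b, y)


def test_crossover_binary_prefix_swap():
    x = np.array([1, 1, 1, 1], dtype=np.uint8)
    y = np.array([0, 0, 0, 0], dtype=np.uint8)
    a, b = crossover_binary(x, y, "single_point", _FixedRNG(2))
    np.testing.assert_array_equal(a, [0, 0, 1, 1])
    np.testing.assert_array_equal(b, [1, 1, 0, 0])


def test_crossover_binary_between_points_swap():
    x = np.array([1, 1, 1, 1, 1], dtype=np.uint8)
    y = np.array([0, 0, 0, 0, 0], dtype=np.uint8)
    a, b = crossover_binary(x, y, "two_point", _FixedRNG(0, 4))
    np.testing.assert_array_equal(a, [1, 0, 0, 0, 1])
    np.testing.assert_array_equal(b, [0, 1, 1, 1, 0])


def test_crossover_binary_bit_counts_conserved(rng):
    for _ in range(10_000):
        x = rng.integers(0, 2, 8).astype(np.uint8)
        y = rng.integers(0, 2, 8).astype(np.uint8)
        strat = ("single_point", "two_point")[int(rng.integers(2))]
        a, b = crossover_binary(x, y, strat, rng)
        np.testing.assert_array_equal(a + b, x + y)  # per-position conservation


def test_crossover_binary_length_mismatch(rng):
    from tdssgrn.evolution import IncompatibleParentsError
    with pytest.raises(IncompatibleParentsError):
        crossover_binary(np.zeros(4, np.uint8), np.zeros(5, np.uint8),
                         "single_point", rng)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_roulette_symmetric(rng):
    pop = ["a", "b"]
    picks = roulette_select(pop, [1.0, 1.0], 2.0, 100_000, rng)
    n_a = picks.count("a")
    se = np.sqrt(0.25 * 100_000)
    assert abs(n_a - 50_000) < 3 * se


def test_roulette_proportional(rng):
    pop = ["a", "b"]
    picks = roulette_select(pop, [3.0, 1.0], 4.0, 100_000, rng)
    n_a = picks.count("a")
    se = np.sqrt(0.75 * 0.25 * 100_000)
    assert abs(n_a - 75_000) < 3 * se


def test_roulette_single_chromosome(rng):
    assert roulette_select(["x"], [0.7], 0.7, 10, rng) == ["x"] * 10


def test_roulette_zero_fitness_uniform_fallback(rng, caplog):
    picks = roulette_select(["a", "b"], [0.0, 0.0], 0.0, 1000, rng)
    assert 0 < picks.count("a") < 1000  # both get picked


# ---------------------------------------------------------------------------
# whole-chromosome operators preserve invariants
# ---------------------------------------------------------------------------

@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_chromosome_operators_preserve_invariants(seed):
    rng = np.random.default_rng(seed)
    ab = SymbolAlphabet(arities=(2, 3), n_genes=4)
    iv = ParamIntervals()
    cfg = EvolutionConfig(population_size=4, function_set=(2, 3),
                          head_length=2, seed=seed)
    x = random_chromosome(ab, 2, iv, rng)
    y = random_chromosome(ab, 2, iv, rng)
    a, b = crossover_chromosomes(x, y, cfg, int(rng.integers(50)), rng)
    a = mutate_chromosome(a, cfg, rng)
    b = mutate_chromosome(b, cfg, rng)
    for c in (a, b):
        c.gene1.validate(iv)
        c.gene2.validate(iv)
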
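"""Multipoint HMM, allele-sharing scores, and the one-parameter LOD."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stratlink as sl
from stratlink.linkage import (
    LinkageError,
    build_layout,
    kong_cox_curve,
    kong_cox_lod,
    lander_green_ibd,
    npl_pairs,
    s_pairs_vector,
)

from conftest import make_individual, make_nuclear


# ---------------------------------------------------------------------------
# independent oracle: exhaustive joint enumeration over inheritance paths


def _oracle_labels(ped, bits):
    """Founder-allele labels per individual via recursive descent.

    Shares only the bit-order convention with the implementation (two bits
    per non-founder in topological sorted order, paternal first, 0 meaning
    the parent passed its own paternal allele).
    """
    founders = [m.indiv_id for m in ped.founders]
    topo = ped.topological_nonfounders()
    bit_of = {}
    for j, ind in enumerate(topo):
        bit_of[(ind.indiv_id, "p")] = bits[2 * j]
        bit_of[(ind.indiv_id, "m")] = bits[2 * j + 1]

    def labels(iid):
        if iid in founders:
            i = founders.index(iid)
            return (2 * i, 2 * i + 1)
        ind = ped.members[iid]
        from_father = labels(ind.father_id)[bit_of[(iid, "p")]]
        from_mother = labels(ind.mother_id)[bit_of[(iid, "m")]]
        return (from_father, from_mother)

    return {iid: labels(iid) for iid in ped.members}


def _oracle_emission(ped, bits, marker, freqs):
    """Emission by explicit loops over founder-allele assignments."""
    founders = [m.indiv_id for m in ped.founders]
    labels = _oracle_labels(ped, bits)
    codes = sorted(freqs)
    total = 0.0
    for assign in itertools.product(codes, repeat=2 * len(founders)):
        prob = 1.0
        for a in assign:
            prob *= freqs[a]
        ok = True
        for iid, ind in ped.members.items():
            g = ind.genotypes[marker]
            if g[0] == 0:
                continue
            la, lb = labels[iid]
            pair = sorted((assign[la], assign[lb]))
            if pair != sorted((int(g[0]), int(g[1]))):
                ok = False
                break
        if ok:
            total += prob
    return total


def oracle_joint_posterior(ped, mmap, freqs):
    """Marginal inheritance-vector posteriors from the full joint over all
    marker positions (transition matrices built from bit-flip counts)."""
    topo = ped.topological_nonfounders()
    n_bits = 2 * len(topo)
    V = 2 ** n_bits
    all_bits = [
        tuple((v >> k) & 1 for k in range(n_bits)) for v in range(V)
    ]
    posts = []
    for chrom in np.unique(mmap.chromosomes):
        idx = mmap.chromosome_indices(chrom)
        pos = mmap.positions_cm[idx]
        emis = np.array(
            [[_oracle_emission(ped, b, int(m), freqs[int(m)]) for b in all_bits]
             for m in idx]
        )
        joint = emis[0] / V
        for j in range(1, len(idx)):
            theta = sl.haldane_theta(float(pos[j] - pos[j - 1]))
            trans = np.empty((V, V))
            for a in range(V):
                for b in range(V):
                    flips = bin(a ^ b).count("1")
                    trans[a, b] = theta**flips * (1 - theta) ** (n_bits - flips)
            # joint over the path collapses to a forward product because the
            # chain is Markov; keep the full path tensor for <=3 markers
            joint = np.einsum("...a,ab->...ab", joint, trans) * emis[j]
        flat = joint.reshape(-1)
        norm = flat.sum()
        marg = []
        for j in range(len(idx)):
            axes = tuple(k for k in range(len(idx)) if k != j)
            marg.append(joint.sum(axis=axes) / norm)
        posts.append(np.array(marg))
    return np.vstack(posts)


def random_small_pedigree(rng, freqs):
    """Random nuclear (1-3 kids) or three-generation family with genotypes
    produced by explicit gene-dropping, then randomly masked."""
    n_markers = len(freqs)
    codes = sorted(freqs[0])
    probs = [freqs[0][c] for c in codes]

    def founder_geno():
        return rng.choice(codes, size=(n_markers, 2), p=probs).astype(np.int16)

    def drop(fg, mg):
        out = np.empty((n_markers, 2), dtype=np.int16)
        for m in range(n_markers):
            out[m, 0] = fg[m, rng.integers(0, 2)]
            out[m, 1] = mg[m, rng.integers(0, 2)]
        return out

    if rng.random() < 0.7:
        n_kids = int(rng.integers(1, 4))
        fg, mg = founder_geno(), founder_geno()
        kids = [
            (f"S{i+1}", "male" if rng.random() < 0.5 else "female", "affected",
             drop(fg, mg))
            for i in range(n_kids)
        ]
        ped = make_nuclear("FX", (fg, mg), kids)
    else:
        # grandparents -> mother; father marries in: 2 non-founders
        gpg, gmg = founder_geno(), founder_geno()
        mo_g = drop(gpg, gmg)
        fa_g = founder_geno()
        child_g = drop(fa_g, mo_g)
        members = {
            "GP": make_individual("FX", "GP", "0", "0", "male", "unknown", gpg),
            "GM": make_individual("FX", "GM", "0", "0", "female", "unknown", gmg),
            "MO": make_individual("FX", "MO", "GP", "GM", "female", "unaffected", mo_g),
            "FA": make_individual("FX", "FA", "0", "0", "male", "unaffected", fa_g),
            "S1": make_individual("FX", "S1", "FA", "MO", "male", "affected", child_g),
        }
        ped = sl.Pedigree("FX", members)
        ped.validate()
    # random masking, keeping at least one typed genotype per marker
    for ind in ped.members.values():
        mask = rng.random(n_markers) < 0.2
        ind.genotypes[mask] = 0
    return ped


def _random_map(rng, n_markers):
    pos = np.sort(rng.uniform(0, 40, size=n_markers))
    while np.any(np.diff(pos) <= 1e-3):
        pos = np.sort(rng.uniform(0, 40, size=n_markers))
    maf = rng.uniform(0.2, 0.5)
    freqs = [{1: 1 - maf, 2: maf} for _ in range(n_markers)]
    return (
        sl.MarkerMap(
            [f"m{i}" for i in range(n_markers)],
            np.ones(n_markers, dtype=int),
            pos,
            allele_freqs=freqs,
        ),
        freqs,
    )


def test_hmm_posterior_matches_joint_enumeration_sample():
    rng = np.random.default_rng(123)
    for _ in range(12):
        n_markers = int(rng.integers(1, 4))
        mmap, freqs = _random_map(rng, n_markers)
        ped = random_small_pedigree(rng, freqs)
        dist = lander_green_ibd(ped, mmap, freqs)
        want = oracle_joint_posterior(ped, mmap, freqs)
        np.testing.assert_allclose(dist.posterior, want, atol=1e-8)


def test_single_marker_untyped_parents_equals_enumeration():
    # both sibs 1/1, allele-1 frequency 0.5, parents untyped
    g = lambda a, b: np.array([[a, b]], dtype=np.int16)
    ped = make_nuclear(
        "F1",
        (g(0, 0), g(0, 0)),
        [("S1", "male", "affected", g(1, 1)), ("S2", "male", "affected", g(1, 1))],
    )
    freqs = [{1: 0.5, 2: 0.5}]
    mmap = sl.MarkerMap(["m1"], np.array([1]), np.array([0.0]), allele_freqs=freqs)
    dist = lander_green_ibd(ped, mmap, freqs)
    want = oracle_joint_posterior(ped, mmap, freqs)
    np.testing.assert_allclose(dist.posterior, want, atol=1e-12)


def test_fully_informative_marker_gives_ibd2():
    g = lambda a, b: np.array([[a, b]], dtype=np.int16)
    ped = make_nuclear(
        "F1",
        (g(1, 2), g(3, 4)),
        [("S1", "male", "affected", g(1, 3)), ("S2", "male", "affected", g(1, 3))],
    )
    freqs = [{1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}]
    mmap = sl.MarkerMap(["m1"], np.array([1]), np.array([0.0]), allele_freqs=freqs)
    dist = lander_green_ibd(ped, mmap, freqs)
    s = s_pairs_vector(dist.layout, ["S1", "S2"])
    assert dist.posterior[0] @ s == pytest.approx(2.0)


def test_distant_position_relaxes_to_uniform_prior():
    g = lambda a, b: np.array([[a, b]], dtype=np.int16)
    ped = make_nuclear(
        "F1",
        (g(1, 2), g(3, 4)),
        [("S1", "male", "affected", g(1, 3)), ("S2", "male", "affected", g(1, 3))],
    )
    freqs = [{1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}]
    mmap = sl.MarkerMap(["m1"], np.array([1]), np.array([0.0]), allele_freqs=freqs)
    dist = lander_green_ibd(
        ped, mmap, freqs, extra_positions={1: np.array([500.0])}
    )
    # position 500 cM away: posterior must be (near) uniform, Z near 0
    far = dist.posterior[-1]
    np.testing.assert_allclose(far, np.full(16, 1 / 16), atol=1e-6)
    npl = npl_pairs(ped, dist, ["S1", "S2"])
    assert abs(npl.z[-1]) < 1e-5


def test_meiosis_budget_raises():
    rng = np.random.default_rng(0)
    g = rng.integers(1, 3, size=(1, 2)).astype(np.int16)
    kids = [
        (f"S{i}", "male", "affected", rng.integers(1, 3, size=(1, 2)).astype(np.int16))
        for i in range(10)
    ]
    ped = make_nuclear("F1", (g.copy(), g.copy()), kids)
    freqs = [{1: 0.5, 2: 0.5}]
    mmap = sl.MarkerMap(["m1"], np.array([1]), np.array([0.0]), allele_freqs=freqs)
    with pytest.raises(LinkageError, match="meiosis bits"):
        lander_green_ibd(ped, mmap, freqs, max_meiosis_bits=16)


def test_zero_likelihood_names_family_and_marker():
    g = lambda a, b: np.array([[a, b]], dtype=np.int16)
    ped = make_nuclear(
        "F9", (g(1, 1), g(1, 1)), [("S1", "male", "affected", g(2, 2))]
    )
    freqs = [{1: 0.5, 2: 0.5}]
    mmap = sl.MarkerMap(["mz"], np.array([1]), np.array([0.0]), allele_freqs=freqs)
    with pytest.raises(LinkageError, match="F9.*mz"):
        lander_green_ibd(ped, mmap, freqs)


# ---------------------------------------------------------------------------
# S_pairs scoring


def test_asp_null_moments_and_z():
    g = lambda a, b: np.array([[a, b]], dtype=np.int16)
    ped = make_nuclear(
        "F1",
        (g(1, 2), g(3, 4)),
        [("S1", "male", "affected", g(1, 3)), ("S2", "male", "affected", g(1, 3))],
    )
    layout = build_layout(ped)
    s = s_pairs_vector(layout, ["S1", "S2"])
    assert s.mean() == pytest.approx(1.0)
    assert s.std() == pytest.approx(np.sqrt(0.5))
    freqs = [{1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}]
    mmap = sl.MarkerMap(["m1"], np.array([1]), np.array([0.0]), allele_freqs=freqs)
    dist = lander_green_ibd(ped, mmap, freqs)
    npl = npl_pairs(ped, dist, ["S1", "S2"])
    assert npl.z[0] == pytest.approx(np.sqrt(2.0))


def test_uninformative_family_flagged():
    g = lambda a, b: np.array([[a, b]], dtype=np.int16)
    ped = make_nuclear("F1", (g(1, 2), g(3, 4)), [("S1", "male", "affected", g(1, 3))])
    layout = build_layout(ped)
    with pytest.raises(LinkageError):
        s_pairs_vector(layout, ["S1"])


def test_sib_trio_s_pairs_is_pairwise_sum():
    rng = np.random.default_rng(4)
    g = lambda: rng.integers(1, 3, size=(1, 2)).astype(np.int16)
    fg, mg = g(), g()
    kids = [(f"S{i+1}", "male", "affected",
             np.array([[fg[0, rng.integers(0, 2)], mg[0, rng.integers(0, 2)]]],
                      dtype=np.int16))
            for i in range(3)]
    ped = make_nuclear("F1", (fg, mg), kids)
    layout = build_layout(ped)
    s = s_pairs_vector(layout, ["S1", "S2", "S3"])
    from stratlink.linkage import _pair_ibd_vector

    brute = sum(
        _pair_ibd_vector(layout, a, b)
        for a, b in itertools.combinations(["S1", "S2", "S3"], 2)
    )
    np.testing.assert_array_equal(s, brute)


def test_s_all_equals_closed_form_for_sib_pair():
    # for two siblings S_all = 1 + IBD/4: of the four allele picks, exactly
    # IBD of them select the same founder allele from both sibs, doubling
    # that pick's factorial weight; so S_all and S_pairs are affinely related
    g = lambda a, b: np.array([[a, b]], dtype=np.int16)
    ped = make_nuclear(
        "F1",
        (g(1, 2), g(3, 4)),
        [("S1", "male", "affected", g(1, 3)), ("S2", "male", "affected", g(1, 3))],
    )
    layout = build_layout(ped)
    from stratlink.linkage import s_all_vector

    s_all = s_all_vector(layout, ["S1", "S2"])
    s_prs = s_pairs_vector(layout, ["S1", "S2"])
    np.testing.assert_allclose(s_all, 1.0 + 0.25 * s_prs)


def test_scores_invariant_under_allele_relabeling():
    rng = np.random.default_rng(11)
    n_markers = 5
    mmap, freqs = _random_map(rng, n_markers)
    ped = random_small_pedigree(rng, freqs)
    while len([i for i in ped.members.values() if i.affection == "affected"]) < 2:
        ped = random_small_pedigree(rng, freqs)
    affected = [i.indiv_id for i in ped.members.values() if i.affection == "affected"]
    dist = lander_green_ibd(ped, mmap, freqs)
    z1 = npl_pairs(ped, dist, affected).z
    # swap allele codes 1 <-> 2 everywhere (genotypes and frequencies)
    for ind in ped.members.values():
        gswap = ind.genotypes.copy()
        gswap[gswap == 1] = 9
        gswap[gswap == 2] = 1
        gswap[gswap == 9] = 2
        ind.genotypes = gswap
    freqs2 = [{1: f[2], 2: f[1]} for f in freqs]
    dist2 = lander_green_ibd(ped, mmap, freqs2)
    z2 = npl_pairs(ped, dist2, affected).z
    np.testing.assert_allclose(z1, z2, atol=1e-10)


# ---------------------------------------------------------------------------
# Kong-Cox LOD


def grid_search_lod(z, step=1e-5, cap=2.0):
    """Independent dense-grid maximization over the same delta interval."""
    z = np.asarray(z, dtype=float)
    neg = z[z < 0]
    hi = min(cap, 0.999999 / np.abs(neg).max()) if neg.size else cap
    deltas = np.arange(0.0, hi + step, step)
    deltas = deltas[deltas <= hi]
    vals = np.log10(1.0 + deltas[:, None] * z[None, :]).sum(axis=1)
    k = int(vals.argmax())
    return float(deltas[k]), float(max(vals[k], 0.0))


def test_kong_cox_worked_examples():
    assert kong_cox_lod([0.0, 0.0, 0.0]) == (0.0, 0.0)
    d, lod = kong_cox_lod([1.0, -1.0])
    assert lod == pytest.approx(0.0, abs=1e-10)
    d, lod = kong_cox_lod([2.0, -0.5])
    assert d == pytest.approx(0.75, abs=1e-4)
    gd, glod = grid_search_lod([2.0, -0.5])
    assert lod == pytest.approx(glod, abs=1e-4)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=-4.0, max_value=4.0, allow_nan=False),
        min_size=1,
        max_size=20,
    )
)
def test_kong_cox_matches_grid_search_property(z):
    d, lod = kong_cox_lod(z)
    gd, glod = grid_search_lod(z)
    assert lod == pytest.approx(glod, abs=1e-4)
    assert lod >= 0.0


def test_kong_cox_invariant_to_family_order():
    rng = np.random.default_rng(2)
    z = rng.normal(size=12)
    d1, l1 = kong_cox_lod(z)
    d2, l2 = kong_cox_lod(z[::-1])
    assert l1 == pytest.approx(l2, abs=1e-10)


def test_kong_cox_curve_matches_scalar():
    rng = np.random.default_rng(8)
    zmat = rng.normal(size=(10, 7))
    deltas, lods = kong_cox_curve(zmat)
    for j in range(7):
        d, lod = kong_cox_lod(zmat[:, j])
        assert lods[j] == pytest.approx(lod, abs=1e-8)


# ---------------------------------------------------------------------------
# LOD -> pointwise p


def test_lod_to_pvalue_examples_and_monotonicity():
    assert sl.lod_to_pvalue(0.0) == pytest.approx(0.5)
    assert f"{sl.lod_to_pvalue(1.41):.3f}" == "0.005"
    assert f"{sl.lod_to_pvalue(3.50):.5f}" == "0.00003"
    lods = np.linspace(0, 6, 200)
    p = sl.lod_to_pvalue(lods)
    assert np.all(np.diff(p) < 0)
    with pytest.raises(LinkageError):
        sl.lod_to_pvalue(-0.1)


# ---------------------------------------------------------------------------
# genome scan plumbing


def test_scan_single_family_cohort(small_cohort):
    pedigrees, mmap, table, _ = small_cohort
    ped = pedigrees[0]
    cohort = sl.StratifiedCohort(
        "ONE", "n2", {ped.family_id: frozenset(ped.affected_ids)}
    )
    engine = sl.MultipointEngine(pedigrees, mmap)
    curve = engine.scan(cohort)
    assert curve.n_families == 1
    z = engine.z_curve(ped.family_id, frozenset(ped.affected_ids))
    d, lod = kong_cox_lod([z[0]])
    assert curve.lod[0] == pytest.approx(lod, abs=1e-8)
    assert len(curve.lod) == len(mmap)
    np.testing.assert_allclose(curve.pointwise_p, sl.lod_to_pvalue(curve.lod))


def test_scan_family_order_invariance(small_cohort):
    pedigrees, mmap, table, _ = small_cohort
    cat = sl.build_catalogue(pedigrees, table, stage="n2")
    e1 = sl.MultipointEngine(pedigrees, mmap)
    e2 = sl.MultipointEngine(list(reversed(pedigrees)), mmap)
    c1 = e1.scan(cat["ALL"])
    c2 = e2.scan(cat["ALL"])
    np.testing.assert_allclose(c1.lod, c2.lod, atol=1e-9)
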
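import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ecfmap.conservation import (ConservationParams, Proteome, SpeciesData,
                                 align_protein, conservation_matrix,
                                 conserved_targets, rbh_orthologs)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n=80):
    return "".join(AA[i] for i in rng.integers(0, 20, n))


# ---------------------------------------------------------------------------
# alignment

def test_identical_sequences_align_perfectly():
    rng = np.random.default_rng(0)
    seq = _random_protein(rng, 100)
    identity, coverage, score = align_protein(seq, seq)
    assert identity == pytest.approx(100.0)
    assert coverage == pytest.approx(100.0)
    assert score > 0


def test_reversed_sequence_scores_far_lower():
    rng = np.random.default_rng(1)
    seq = _random_protein(rng, 80)
    score_self = align_protein(seq, seq)[2]
    score_rev = align_protein(seq, seq[::-1])[2]
    assert score_rev < 0.5 * score_self


def test_align_rejects_bad_characters():
    with pytest.raises(ValueError):
        align_protein("ACDE", "AC1E")
    with pytest.raises(ValueError):
        align_protein("", "ACDE")


def _gotoh_local_score(a, b, open_gap=-11.0, extend_gap=-1.0):
    """Independent affine-gap Smith-Waterman (Gotoh) oracle."""
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)   # gap in b
    Iy = np.full((n + 1, m + 1), NEG)   # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0,
                          M[i - 1, j - 1] + s,
                          Ix[i - 1, j - 1] + s,
                          Iy[i - 1, j - 1] + s)
            Ix[i, j] = max(M[i - 1, j] + open_gap, Ix[i - 1, j] + extend_gap)
            Iy[i, j] = max(M[i, j - 1] + open_gap, Iy[i, j - 1] + extend_gap)
            best = max(best, M[i, j])
    return best


@pytest.mark.parametrize("seed", range(5))
def test_alignment_score_matches_dp_oracle(seed):
    rng = np.random.default_rng(seed)
    a = _random_protein(rng, 8)
    b = _random_protein(rng, 9)
    assert align_protein(a, b)[2] == pytest.approx(_gotoh_local_score(a, b))


# ---------------------------------------------------------------------------
# reciprocal best hits

def _proteome(species, seqs):
    return Proteome(species, {f"{species}_p{i}": s for i, s in enumerate(seqs)},
                    {f"{species}_p{i}": f"g{i}" for i in range(len(seqs))})


def test_identical_proteomes_map_one_to_one():
    rng = np.random.default_rng(3)
    seqs = [_random_protein(rng) for _ in range(6)]
    ref = _proteome("ref", seqs)
    other = _proteome("sp", seqs)
    pairs = rbh_orthologs(ref, other)
    assert len(pairs) == 6
    for i in range(6):
        assert pairs[f"ref_p{i}"].other_protein == f"sp_p{i}"
        assert pairs[f"ref_p{i}"].identity == pytest.approx(100.0)


def test_lost_gene_is_absent_from_mapping():
    rng = np.random.default_rng(4)
    seqs = [_random_protein(rng) for _ in range(5)]
    ref = _proteome("ref", seqs)
    other = _proteome("sp", seqs[:3])  # species lost genes 3 and 4
    pairs = rbh_orthologs(ref, other)
    assert set(pairs) == {"ref_p0", "ref_p1", "ref_p2"}


def test_paralog_only_mutual_best_recorded():
    rng = np.random.default_rng(5)
    base = _random_protein(rng, 60)
    # ref has one gene; other has the ortholog plus a diverged paralog
    mutated = list(base)
    for i in rng.integers(0, 60, 12):
        mutated[i] = AA[rng.integers(0, 20)]
    ref = Proteome("ref", {"r0": base}, {"r0": "g0"})
    other = Proteome("sp", {"o0": base, "o1": "".join(mutated)},
                     {"o0": "g0", "o1": "g1"})
    pairs = rbh_orthologs(ref, other)
    assert pairs["r0"].other_protein == "o0"


def test_rbh_symmetric_under_swap():
    rng = np.random.default_rng(6)
    seqs = [_random_protein(rng) for _ in range(4)]
    mutated = []
    for s in seqs:
        chars = list(s)
        for i in rng.integers(0, len(s), 6):
            chars[i] = AA[rng.integers(0, 20)]
        mutated.append("".join(chars))
    a = _proteome("a", seqs)
    b = _proteome("b", mutated)
    ab = {(p.ref_protein.split("_p")[1], p.other_protein.split("_p")[1])
          for p in rbh_orthologs(a, b).values()}
    ba = {(p.other_protein.split("_p")[1], p.ref_protein.split("_p")[1])
          for p in rbh_orthologs(b, a).values()}
    assert ab == ba


# ---------------------------------------------------------------------------
# conservation matrix

def test_self_panel_reproduces_reference(validated_pwms):
    from ecfmap.synthetic_data import SimConfig, simulate_genome_with_sites
    cfg = SimConfig(seed=21, n_genes=8, distance_range=(20, 160))
    truth = simulate_genome_with_sites(cfg)
    targets = list(truth.sites.gene_id)
    panel = [SpeciesData("copy", truth.contigs, truth.genes,
                         Proteome("copy", truth.proteome.proteins,
                                  truth.proteome.gene_link))]
    m = conservation_matrix(targets, truth.species, panel, validated_pwms,
                            ConservationParams(min_genomes=1, panel_size=1))
    assert (m.states.loc[targets, "copy"] == "site").all()
    assert m.scores.notna().all().all()


def test_empty_target_list_gives_empty_matrix(validated_pwms):
    from ecfmap.synthetic_data import SimConfig, simulate_genome_with_sites
    cfg = SimConfig(seed=22, n_genes=4)
    truth = simulate_genome_with_sites(cfg)
    panel = [SpeciesData("copy", truth.contigs, truth.genes, truth.proteome)]
    m = conservation_matrix([], truth.species, panel, validated_pwms,
                            ConservationParams(min_genomes=1, panel_size=1))
    assert m.states.empty


def test_conserved_targets_threshold_arithmetic(validated_pwms):
    import pandas as pd
    from ecfmap.conservation import ConservationMatrix
    states = pd.DataFrame(
        {"s1": ["site", "site"], "s2": ["site", "no_site"],
         "s3": ["site", "absent"]}, index=["t_strong", "t_weak"])
    m = ConservationMatrix(states, pd.DataFrame(
        0.9, index=states.index, columns=states.columns))
    assert conserved_targets(m, 0) == ["t_strong", "t_weak"]
    assert conserved_targets(m, 4) == []
    assert conserved_targets(m, 2) == ["t_strong"]


def test_matrix_export_cell_codes(validated_pwms):
    import pandas as pd
    from ecfmap.conservation import ConservationMatrix
    states = pd.DataFrame({"s1": ["site", "no_site", "absent"]},
                          index=list("abc"))
    scores = pd.DataFrame({"s1": [0.91, np.nan, np.nan]}, index=list("abc"))
    out = ConservationMatrix(states, scores).to_frame()
    assert out.loc["a", "s1"] == "0.9100"
    assert out.loc["b", "s1"] == "no_site"
    assert out.loc["c", "s1"] == "absent"
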
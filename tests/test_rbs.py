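"""The duplex model is cross-checked against an independent re-derivation:
the oracle below re-reads the parameter TSV itself and enumerates helices
with its own logic (regex-free run detection, explicit stack summation).
"""

import importlib.resources

import numpy as np
import pandas as pd
import pytest

from regarch import rbs as rbs_mod
from regarch.io import GeneFeature, GenomeSequence, revcomp
from regarch.rbs import (ANTI_SD, duplex_dg, genome_rbs_summary, load_nn_params,
                         positional_profile, rbs_scan)

PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
WEAK = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}


def _oracle_params():
    ref = importlib.resources.files("regarch.data") / "rna_nn_params.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    stacks = {}
    for r in df.itertuples(index=False):
        if r.kind == "stack":
            t, b = r.key.split("/")
            stacks[(t, b)] = (r.dH, r.dS)
            stacks[(b, t)] = (r.dH, r.dS)
    init = df[df.kind == "init"].iloc[0]
    term = df[df.kind == "terminal"].iloc[0]
    return stacks, (init.dH, init.dS), (term.dH, term.dS)


def oracle_dg(window, T, anti=ANTI_SD):
    """Brute force: every registration, every sub-helix, explicit sums."""
    stacks, (iH, iS), (tH, tS) = _oracle_params()
    q = window.upper().replace("T", "U")
    t_k = T + 273.15
    best = 0.0
    for k in range(len(q) + len(anti) - 1):
        idx = [i for i in range(len(q))
               if 0 <= k - i < len(anti) and (q[i], anti[k - i]) in PAIRS]
        # all contiguous stretches of paired indices, length >= 3
        for a in range(len(idx)):
            for b in range(a + 2, len(idx)):
                span = idx[a:b + 1]
                if span != list(range(span[0], span[-1] + 1)):
                    continue
                dH, dS = iH, iS
                for i in span[:-1]:
                    top = q[i] + q[i + 1]
                    bottom = anti[k - i - 1] + anti[k - i]
                    sH, sS = stacks[(top, bottom)]
                    dH += sH
                    dS += sS
                for end in (span[0], span[-1]):
                    if (q[end], anti[k - end]) in WEAK:
                        dH += tH
                        dS += tS
                best = min(best, dH - t_k * dS / 1000.0)
    return best


PERFECT_SD = "AAGGAGGTGA"  # full complement of the anti-SD


class TestDuplexDG:
    def test_perfect_complement_hand_ledger(self):
        """The full 9-stack helix of the perfect SD, summed by hand from
        the embedded table: stacks AA/UU, AG/CU, CC/GG, GA/UC, AG/CU,
        CC/GG, AC/GU, CA/UG, GA/UC + init + two terminal A-U penalties."""
        dH = (-6.8 - 10.5 - 13.4 - 12.4 - 10.5 - 13.4 - 11.4 - 10.4 - 12.4
              + 3.60 + 2 * 3.70)
        dS = (-19.02 - 27.08 - 32.56 - 32.24 - 27.08 - 32.56 - 29.66 - 26.76
              - 32.24 + (-1.61) + 2 * 10.32)
        expected = dH - (37 + 273.15) * dS / 1000.0
        r = duplex_dg(PERFECT_SD, 37.0)
        assert r.dG == pytest.approx(expected, abs=1e-9)
        assert r.span == (0, 10)

    def test_no_complementary_run_scores_zero(self):
        assert duplex_dg("AAAAAAAAAA", 37.0).dG == 0.0

    def test_hotter_is_weaker(self):
        assert duplex_dg(PERFECT_SD, 80.0).dG > duplex_dg(PERFECT_SD, 37.0).dG

    def test_wrong_length(self):
        with pytest.raises(ValueError, match="10 nt"):
            duplex_dg("ACGTACGT", 37.0)

    def test_temperature_range(self):
        with pytest.raises(ValueError, match="temperature"):
            duplex_dg(PERFECT_SD, 110.0)

    def test_dna_and_rna_inputs_equivalent(self):
        assert duplex_dg("AAGGAGGTGA", 55.0).dG == \
            duplex_dg("AAGGAGGUGA", 55.0).dG

    def test_linear_in_absolute_temperature(self):
        """For a fixed helix dG(T) = dH - T dS is exactly linear; the
        reported minimum is a lower envelope of such lines, hence
        locally linear and globally concave in T."""
        t = np.array([35.0, 37.0, 39.0])  # narrow: helix does not switch
        g = np.array([duplex_dg(PERFECT_SD, float(x)).dG for x in t])
        slope = (g[2] - g[0]) / (t[2] - t[0])
        assert g[1] == pytest.approx(g[0] + slope * 2.0, abs=1e-9)
        wide = [duplex_dg(PERFECT_SD, float(x)).dG for x in (20, 60, 100)]
        assert wide[1] >= (wide[0] + wide[2]) / 2 - 1e-9  # concavity

    @pytest.mark.parametrize("T", [37.0, 80.0])
    def test_matches_bruteforce_on_random_windows(self, T, rng):
        for _ in range(120):
            w = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10))
            assert duplex_dg(w, T).dG == pytest.approx(oracle_dg(w, T),
                                                       abs=1e-9), w

    def test_matches_bruteforce_on_wobble_rich_windows(self):
        # windows pairing G against anti-SD U positions exercise G.U stacks
        for w in ("GGGGAGGGGA", "GAGGGGGTGG", "AGGGAGGGGG", "GGAGGAGGAG"):
            for T in (37.0, 80.0):
                assert duplex_dg(w, T).dG == pytest.approx(
                    oracle_dg(w, T), abs=1e-9)


class TestRBSScan:
    def _make_gene(self, rng, offset=-15, strand="+", sd=PERFECT_SD):
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        up = list(bg[:60])
        # plant the SD so its 5' end sits at `offset` upstream of the ATG
        up[60 + offset: 60 + offset + 10] = sd
        sense = "".join(up) + "ATG" + bg[100:250]
        if strand == "+":
            seq = sense
            gene = GeneFeature("g", 60, len(sense), "+")
        else:
            seq = revcomp(sense)
            gene = GeneFeature("g", 0, len(sense) - 60, "-")
        return GenomeSequence(id="g", sequence=seq, topology="linear"), gene

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_planted_sd_offset_recovered(self, rng, strand):
        genome, gene = self._make_gene(rng, offset=-15, strand=strand)
        rec = rbs_scan(gene, genome, 37.0)
        assert rec.offset == -15
        assert rec.local_min_dG == pytest.approx(
            duplex_dg(PERFECT_SD, 37.0).dG)

    def test_all_a_upstream_scores_zero(self):
        seq = "A" * 60 + "ATG" + "C" * 100
        genome = GenomeSequence(id="g", sequence=seq, topology="linear")
        gene = GeneFeature("g", 60, 163, "+")
        rec = rbs_scan(gene, genome, 80.0)
        assert rec.local_min_dG == 0.0

    def test_truncated_window_flagged(self):
        seq = "ATG" + "C" * 100
        genome = GenomeSequence(id="g", sequence=seq, topology="linear")
        gene = GeneFeature("g", 0, 60, "+")
        assert rbs_scan(gene, genome, 37.0).truncated


class TestPositionalProfile:
    def test_planted_minimum_location(self, small_dataset):
        """The profile minimum sits where 10-mers cover the planted SD
        core (windows starting ~12-16 nt upstream of the start codon)."""
        ds = small_dataset
        cds = [f for f in ds.features if f.kind == "CDS"][:60]
        profile = positional_profile(cds, ds.genome, [37.0], flank=30)
        col = profile[37.0]
        assert -17 <= col.idxmin() <= -10

    def test_monotone_in_temperature(self, small_dataset):
        ds = small_dataset
        cds = [f for f in ds.features if f.kind == "CDS"][:25]
        profile = positional_profile(cds, ds.genome, [65.0, 90.0], flank=20)
        assert np.all(profile[90.0].to_numpy() >= profile[65.0].to_numpy() - 1e-9)

    def test_flat_on_random_genome(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30_000))
        genome = GenomeSequence(id="g", sequence=seq, topology="circular")
        cds = [GeneFeature(f"g{i}", 200 + 600 * i, 600 * i + 500, "+")
               for i in range(40)]
        profile = positional_profile(cds, genome, [37.0], flank=25)
        col = profile[37.0].to_numpy()
        assert col.max() - col.min() < 2.5  # no systematic dip


class TestGenomeSummary:
    def test_single_gene_genome(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
        genome = GenomeSequence(id="g", sequence=seq, topology="circular")
        gene = GeneFeature("g0", 100, 400, "+")
        df = genome_rbs_summary(
            [{"name": "one", "genome": genome, "features": [gene], "ogt": 50}],
            T_eval=37.0)
        assert df.iloc[0]["median_dG"] == pytest.approx(
            rbs_scan(gene, genome, 37.0).local_min_dG)

    def test_duplicated_genome_identical(self, small_dataset):
        ds = small_dataset
        entry = {"name": "x", "genome": ds.genome,
                 "features": ds.features[:30], "ogt": 80}
        df = genome_rbs_summary([entry, dict(entry, name="y")], T_eval=80.0)
        assert df.iloc[0]["median_dG"] == df.iloc[1]["median_dG"]
        assert df.iloc[0]["frac_negative"] == df.iloc[1]["frac_negative"]

    def test_zero_cds_genome_excluded(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
        genome = GenomeSequence(id="g", sequence=seq)
        df = genome_rbs_summary(
            [{"name": "empty", "genome": genome, "features": [], "ogt": 30}],
            T_eval=37.0)
        assert len(df) == 0

    def test_designed_sd_strength_ordering(self):
        """Two genomes built with different SD planting strengths order
        their median dG accordingly."""
        from regarch.simulate import SimulationConfig, simulate_genome_architecture
        strong = simulate_genome_architecture(
            SimulationConfig(seed=21, n_tus=12, sd_mutation_rate=0.0))
        weak = simulate_genome_architecture(
            SimulationConfig(seed=21, n_tus=12, sd_mutation_rate=0.35))
        df = genome_rbs_summary(
            [{"name": "strong", "genome": strong.genome,
              "features": strong.features, "ogt": 80},
             {"name": "weak", "genome": weak.genome,
              "features": weak.features, "ogt": 80}],
            T_eval=37.0)
        med = dict(zip(df["name"], df["median_dG"]))
        assert med["strong"] < med["weak"]


def test_mad_narrows_with_temperature(small_dataset):
    """The spread of local-minimum dG values compresses at 80 C."""
    from regarch.stats import mad
    ds = small_dataset
    cds = [f for f in ds.features if f.kind == "CDS"][:80]
    v37 = np.array([rbs_scan(c, ds.genome, 37.0).local_min_dG for c in cds])
    v80 = np.array([rbs_scan(c, ds.genome, 80.0).local_min_dG for c in cds])
    assert mad(v80) < mad(v37)


def test_parameter_table_complete():
    """Every Watson-Crick and G.U stack is present in both orientations."""
    params = load_nn_params()
    pairs = ["AU", "UA", "CG", "GC", "GU", "UG"]
    for p1 in pairs:
        for p2 in pairs:
            top = p1[0] + p2[0]
            bottom = p2[1] + p1[1]
            assert f"{top}/{bottom}" in params.stacks
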
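"""The synthetic study generator: determinism, planted signals, round trips."""

import numpy as np
import pandas as pd
import pytest

from chromborder import io as cbio
from chromborder.core import GenomicInterval
from chromborder.simulate import (
    TruthManifest,
    generate_boundary_shifts,
    generate_cross,
    generate_expression,
    generate_genes,
    generate_loci,
    generate_sequences,
    generate_tracks,
    simulate_study,
)

GENOME = {"chrA": 60_000, "chrB": 60_000}


class TestGenerateCross:
    def test_no_recombination_gives_constant_chromosomes(self):
        gm = generate_cross(10, GENOME, 5000, recomb_prob=0.0, missing_rate=0.0,
                            seed=1)
        for chrom, grp in gm.spans.groupby("chrom"):
            block = gm.values.loc[grp.index]
            assert (block.nunique(axis=0) == 1).all()

    def test_same_seed_identical(self):
        a = generate_cross(8, GENOME, 5000, seed=3)
        b = generate_cross(8, GENOME, 5000, seed=3)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_flip_fraction_matches_recomb_prob(self):
        p = 0.1
        gm = generate_cross(
            50, {"chrA": 1_005_000}, 5000, recomb_prob=p, missing_rate=0.0, seed=5
        )
        vals = gm.values.to_numpy()  # markers x strains
        flips = np.sum(vals[1:] != vals[:-1])
        n = (vals.shape[0] - 1) * vals.shape[1]
        assert n >= 9_000
        se = np.sqrt(p * (1 - p) / n)
        assert abs(flips / n - p) < 3 * se

    def test_missing_rate_applied(self):
        gm = generate_cross(50, GENOME, 1000, missing_rate=0.2, seed=7)
        frac = (gm.values.to_numpy() == 0.5).mean()
        assert 0.15 < frac < 0.25

    def test_at_least_one_marker_per_chromosome(self):
        gm = generate_cross(4, {"tiny": 100}, marker_spacing=5000, seed=1)
        assert (gm.spans["chrom"] == "tiny").sum() == 1


class TestGenerateLoci:
    def test_deterministic(self):
        a, sa = generate_loci(10, (300, 500), GENOME, seed=2)
        b, sb = generate_loci(10, (300, 500), GENOME, seed=2)
        assert a == b
        pd.testing.assert_series_equal(sa, sb)

    def test_gaps_at_least_min_gap(self):
        loci, _ = generate_loci(20, (300, 500), GENOME, min_gap=1000, seed=3)
        by_chrom = {}
        for l in loci:
            by_chrom.setdefault(l.chrom, []).append(l)
        for group in by_chrom.values():
            group.sort(key=lambda x: x.start)
            for a, b in zip(group, group[1:]):
                assert b.start - a.end >= 1000

    def test_score_mixture_strata(self):
        _, scores = generate_loci(
            300, (300, 500), {f"c{i}": 400_000 for i in range(8)}, seed=4
        )
        low = (scores < 0).mean()
        high = (scores > 0.5).mean()
        assert low + high == 1.0
        se = np.sqrt(0.25 / len(scores))
        assert abs(low - 0.5) < 4 * se

    def test_genome_too_small_errors(self):
        with pytest.raises(ValueError):
            generate_loci(1000, (300, 500), {"chrA": 10_000}, seed=5)


class TestGenerateBoundaryShifts:
    def setup_inputs(self, seed=1, **kwargs):
        gm = generate_cross(20, GENOME, 2000, missing_rate=0.0, seed=seed)
        loci, scores = generate_loci(10, (300, 500), GENOME, seed=seed + 1)
        return gm, loci, scores

    def test_noise_free_group_separation_is_twice_effect(self):
        gm, loci, scores = self.setup_inputs()
        sets, manifest = generate_boundary_shifts(
            loci, scores, gm, n_qtl=4, effect_bp=40, noise_sd_bp=0.0,
            invitro_noise_gain=0.0, seed=3,
        )
        for q in manifest.planted_qtls:
            rid, side = q["trait"].split(":")
            ref = next(l for l in loci if l.id == rid)
            g = gm.values.loc[q["marker"]]
            pos = {
                s: (r.start if side == "5p" else r.end)
                for s, regs in sets.items()
                for r in regs
                if r.id == rid
            }
            by = [pos[s] for s in gm.strains if g[s] == 1.0]
            rm = [pos[s] for s in gm.strains if g[s] == 0.0]
            assert abs(np.mean(by) - np.mean(rm)) == pytest.approx(80.0)
            # BY class anchors at the reference boundary
            assert np.mean(by) == (ref.start if side == "5p" else ref.end)

    def test_no_qtl_no_noise_identity(self):
        gm, loci, scores = self.setup_inputs()
        sets, _ = generate_boundary_shifts(
            loci, scores, gm, n_qtl=0, noise_sd_bp=0.0, invitro_noise_gain=0.0,
            seed=3,
        )
        for regs in sets.values():
            assert [(r.start, r.end) for r in regs] == [
                (l.start, l.end) for l in loci
            ]

    def test_same_seed_identical(self):
        gm, loci, scores = self.setup_inputs()
        s1, m1 = generate_boundary_shifts(loci, scores, gm, n_qtl=3, seed=9)
        s2, m2 = generate_boundary_shifts(loci, scores, gm, n_qtl=3, seed=9)
        assert s1 == s2
        assert m1.planted_qtls == m2.planted_qtls

    def test_cis_trans_marker_placement(self):
        gm, loci, scores = self.setup_inputs()
        _, manifest = generate_boundary_shifts(
            loci, scores, gm, n_qtl=6, cis_fraction=0.5, seed=11
        )
        kinds = [q["kind"] for q in manifest.planted_qtls]
        assert kinds.count("cis") == 3 and kinds.count("trans") == 3
        region_chrom = {l.id: l.chrom for l in loci}
        for q in manifest.planted_qtls:
            mchrom = gm.spans.loc[q["marker"], "chrom"]
            rchrom = region_chrom[q["trait"].split(":")[0]]
            if q["kind"] == "cis":
                assert mchrom == rchrom
            else:
                assert mchrom != rchrom

    def test_score_variance_coupling(self):
        genome = {f"c{i}": 300_000 for i in range(8)}
        gm = generate_cross(40, genome, 5000, missing_rate=0.0, seed=21)
        loci, scores = generate_loci(180, (300, 600), genome, seed=22)
        sets, _ = generate_boundary_shifts(
            loci, scores, gm, n_qtl=0, noise_sd_bp=10.0, invitro_noise_gain=2.0,
            seed=23,
        )
        # per-boundary sample variance of realized positions across strains
        var_by_bid = {}
        for l in loci:
            for side in ("5p", "3p"):
                pos = [
                    (r.start if side == "5p" else r.end)
                    for regs in sets.values()
                    for r in regs
                    if r.id == l.id
                ]
                var_by_bid[f"{l.id}:{side}"] = np.var(pos)
        v = pd.Series(var_by_bid)
        hi = v[scores > 0.5]
        lo = v[scores < 0]
        assert len(hi) >= 150 and len(lo) >= 150
        # sd scales by (1 + 2 * score): expected variance ratio well above 1
        assert hi.mean() / lo.mean() > 2.0


class TestGenerateTracks:
    def test_zero_background_confines_tags(self):
        loci, _ = generate_loci(6, (300, 500), GENOME, seed=31)
        tracks, _ = generate_tracks(loci, GENOME, depth=50, seed=32,
                                    with_sequence=False)
        spans = {c: [] for c in GENOME}
        for l in loci:
            spans[l.chrom].append((l.start, l.end))
        for assay in ("dhs", "faire"):
            for tag in tracks[assay]:
                inside = any(
                    s - tag.length <= tag.position < e
                    for s, e in spans[tag.chrom]
                )
                assert inside

    def test_mnase_midpoints_center_on_planted_dyads(self):
        loci, _ = generate_loci(20, (500, 800), GENOME, seed=33)
        tracks, _ = generate_tracks(
            loci, GENOME, nucleosome_offset_bp=75, depth=200, seed=34,
            with_sequence=False,
        )
        offsets = []
        for l in loci:
            for tag in tracks["mnase"]:
                if tag.chrom != l.chrom:
                    continue
                mid = tag.position + tag.length // 2
                if abs(mid - (l.start + 75)) < 150:
                    # recover fragment midpoint from the 36 bp read
                    frag_mid = (
                        tag.position + 147 // 2
                        if tag.strand == "+"
                        else tag.position + tag.length - 147 // 2
                    )
                    offsets.append(frag_mid - l.start)
        assert len(offsets) > 1000
        assert abs(np.mean(offsets) - 75) <= 5

    def test_same_seed_identical_tags(self):
        loci, _ = generate_loci(4, (300, 500), GENOME, seed=35)
        t1, _ = generate_tracks(loci, GENOME, depth=20, seed=36, with_sequence=False)
        t2, _ = generate_tracks(loci, GENOME, depth=20, seed=36, with_sequence=False)
        assert t1 == t2

    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError):
            generate_tracks([], GENOME, depth=0)

    def test_boundary_cg_excess_planted(self):
        loci, _ = generate_loci(30, (400, 600), GENOME, seed=37)
        seqs = generate_sequences(GENOME, loci, cg_excess=1.5, seed=38)
        def cg_fraction(windows):
            n_in = n = 0
            for w in windows:
                for i in range(len(w) - 1):
                    n += 1
                    n_in += w[i] in "CG" and w[i + 1] in "CG"
            return n_in / n
        boundary = []
        background = []
        for l in loci:
            s = seqs[l.chrom]
            for edge in (l.start, l.end):
                boundary.append(s[edge - 60 : edge + 60])
            background.append(s[l.start - 900 : l.start - 500])
        ratio = cg_fraction(boundary) / cg_fraction(background)
        assert 1.3 < ratio < 1.7


class TestGenerateExpression:
    def setup_study(self, **overrides):
        cfg = {"n_loci": 40, "n_genes": 20, "n_qtl": 5, "n_strains": 96}
        cfg.update(overrides)
        return simulate_study(cfg, seed=41)

    def test_planted_correlation_near_target(self):
        study = self.setup_study(target_r=0.6)
        tr = study["traits"]
        rs = []
        for e in study["manifest"].expression_effects:
            t = tr.values.loc[e["trait"], tr.strains].to_numpy()
            x = study["expression"].loc[e["gene"], tr.strains].to_numpy()
            rs.append(np.corrcoef(t, x)[0, 1])
        assert len(rs) >= 10
        assert abs(np.mean(rs) - 0.6) < 0.1

    def test_zero_target_r_independent(self):
        study = self.setup_study(target_r=0.0)
        assert study["manifest"].expression_effects == []
        tr = study["traits"]
        g = study["genes"][0]
        x = study["expression"].loc[g.id, tr.strains].to_numpy()
        t = tr.values.iloc[0].to_numpy()
        assert abs(np.corrcoef(t, x)[0, 1]) < 0.25

    def test_exact_correlation_without_noise(self):
        study = self.setup_study(target_r=1.0, expression_noise_sd=0.0)
        e = study["manifest"].expression_effects[0]
        tr = study["traits"]
        t = tr.values.loc[e["trait"], tr.strains].to_numpy()
        x = study["expression"].loc[e["gene"], tr.strains].to_numpy()
        assert np.corrcoef(t, x)[0, 1] == pytest.approx(1.0)

    def test_inconsistent_target_errors(self):
        gm = generate_cross(6, GENOME, 5000, seed=1)
        loci, scores = generate_loci(4, (300, 500), GENOME, seed=2)
        sets, _ = generate_boundary_shifts(loci, scores, gm, n_qtl=0, seed=3)
        from chromborder.variation import build_boundary_traits

        traits = build_boundary_traits(loci, sets, 150)
        genes, facing = generate_genes(loci, 2, seed=4)
        with pytest.raises(ValueError):
            generate_expression(
                genes, loci, traits, gm, target_r=1.0, noise_sd=1.0, seed=5
            )

    def test_deterministic(self):
        a = self.setup_study()
        b = self.setup_study()
        pd.testing.assert_frame_equal(a["expression"], b["expression"])


class TestStudyRoundTrip:
    def test_emitted_files_reload_losslessly(self, tmp_path):
        study = simulate_study(
            {"n_loci": 12, "n_genes": 5, "n_qtl": 2, "n_strains": 10}, tmp_path,
            seed=51,
        )
        loci = cbio.read_bed(tmp_path / "reference_loci.bed")
        assert [(l.chrom, l.start, l.end, l.id) for l in loci] == [
            (l.chrom, l.start, l.end, l.id) for l in study["loci"]
        ]
        geno = cbio.read_matrix(tmp_path / "genotypes.tsv")
        pd.testing.assert_frame_equal(geno, study["genotypes"].values)
        traits = cbio.read_matrix(tmp_path / "boundary_traits.tsv")
        pd.testing.assert_frame_equal(traits, study["traits"].values)
        tags = cbio.read_tags(tmp_path / "tags_mnase.bed")
        assert tags == study["tracks"]["mnase"]
        seqs = cbio.read_fasta(tmp_path / "genome.fasta")
        assert seqs == study["sequences"]
        manifest = TruthManifest.from_json(tmp_path / "manifest.json")
        assert manifest.planted_qtls == study["manifest"].planted_qtls
        strain = study["genotypes"].strains[0]
        regs = cbio.read_bed(tmp_path / "strains" / f"{strain}.bed")
        assert [(r.start, r.end) for r in regs] == [
            (r.start, r.end) for r in study["strain_sets"][strain]
        ]
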
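import numpy as np
import pandas as pd
import pytest

from slocus_kit.expression import (
    ExpressionMatrix,
    counts_to_tpm,
    fold_difference,
    tissue_specificity,
    tukey_groups,
)

TISSUES = ("style_stigma", "stamen", "pollen")


def _matrix(counts: dict, lengths=None, n_reps=2):
    samples = [f"{t}_r{i}" for t in TISSUES for i in range(n_reps)]
    tissue = {s: s.rsplit("_r", 1)[0] for s in samples}
    df = pd.DataFrame(counts, index=samples).T
    df.columns = samples
    return ExpressionMatrix(
        counts=df,
        tissue=tissue,
        lengths=lengths or {g: 1000.0 for g in counts},
    )


class TestTpm:
    def test_equal_counts_equal_lengths(self):
        m = _matrix({"a": [10] * 6, "b": [10] * 6})
        tpm = counts_to_tpm(m)
        assert np.allclose(tpm.values, 500_000.0)

    def test_zero_count_zero_tpm(self):
        m = _matrix({"a": [0] * 6, "b": [10] * 6})
        assert (counts_to_tpm(m).loc["a"] == 0).all()

    def test_column_sums_to_million(self):
        rng = np.random.default_rng(0)
        m = _matrix(
            {f"g{i}": rng.integers(0, 500, size=6).tolist() for i in range(20)},
            lengths={f"g{i}": float(rng.integers(200, 3000)) for i in range(20)},
        )
        sums = counts_to_tpm(m).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_scale_invariance(self):
        m1 = _matrix({"a": [5] * 6, "b": [10] * 6})
        m2 = _matrix({"a": [10] * 6, "b": [20] * 6})
        assert np.allclose(counts_to_tpm(m1).values, counts_to_tpm(m2).values)

    def test_all_zero_sample_warns(self):
        m = _matrix({"a": [0, 1, 1, 1, 1, 1], "b": [0, 2, 2, 2, 2, 2]})
        with pytest.warns(UserWarning, match="all-zero"):
            tpm = counts_to_tpm(m)
        assert (tpm.iloc[:, 0] == 0).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _matrix({"a": [-1] * 6})

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            _matrix({"a": [1] * 6}, lengths={"a": 0.0})


def _tpm_df(style, stamen, pollen, gene="g1"):
    cols = {}
    for t, vals in zip(TISSUES, (style, stamen, pollen)):
        for i, v in enumerate(vals):
            cols[f"{t}_r{i}"] = v
    return pd.DataFrame(cols, index=[gene]), {s: s.rsplit("_r", 1)[0] for s in cols}


class TestSpecificity:
    def test_style_specific(self):
        tpm, tissue = _tpm_df([300, 300], [0.2, 0.2], [0.1, 0.1])
        p = tissue_specificity(tpm, tissue, "g1")
        assert p.profile == "style_specific"

    def test_all_zero_silent(self):
        tpm, tissue = _tpm_df([0, 0], [0, 0], [0, 0])
        assert tissue_specificity(tpm, tissue, "g1").profile == "silent"

    def test_male_specific(self):
        tpm, tissue = _tpm_df([0.1, 0.1], [50, 60], [80, 90])
        assert tissue_specificity(tpm, tissue, "g1").profile == "male_specific"

    def test_missing_tissue_error(self):
        tpm, tissue = _tpm_df([1, 1], [1, 1], [1, 1])
        sub = {s: t for s, t in tissue.items() if t != "pollen"}
        with pytest.raises(ValueError, match="pollen"):
            tissue_specificity(tpm[list(sub)], sub, "g1")

    def test_monotone_in_focal_mean(self):
        """Raising the style mean never demotes a style-specific gene."""
        for style in (10, 50, 500, 5000):
            tpm, tissue = _tpm_df([style, style], [0.2, 0.2], [0.1, 0.1])
            assert tissue_specificity(tpm, tissue, "g1").profile == "style_specific"

    def test_planted_30x_fold_on_exact_means(self):
        tpm = pd.DataFrame(
            {
                "style_stigma_r0": [3000.0, 100.0],
                "style_stigma_r1": [3000.0, 100.0],
                "stamen_r0": [0.0, 0.0],
                "stamen_r1": [0.0, 0.0],
                "pollen_r0": [0.0, 0.0],
                "pollen_r1": [0.0, 0.0],
            },
            index=["hi", "lo"],
        )
        tissue = {s: s.rsplit("_r", 1)[0] for s in tpm.columns}
        fold = fold_difference(tpm, tissue, "hi", "lo")
        assert fold == pytest.approx(3000.5 / 100.5, rel=1e-12)


class TestTukey:
    def test_identical_groups_share_letter(self):
        groups = {g: np.array([5.0, 5.0, 5.0]) for g in "abcd"}
        res = tukey_groups(groups)
        assert set(res.letters.values()) == {"a"}

    def test_two_separated_groups_distinct(self):
        rng = np.random.default_rng(2)
        groups = {
            "high": 10 + rng.normal(0, 0.1, 3),
            "low": rng.normal(0, 0.1, 3),
        }
        res = tukey_groups(groups, log_transform=False)
        assert set(res.letters["high"]) & set(res.letters["low"]) == set()

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(i, 0.5, 4) for i in range(4)}
        r1 = tukey_groups(dict(sorted(groups.items())), log_transform=False)
        r2 = tukey_groups(dict(sorted(groups.items(), reverse=True)), log_transform=False)
        assert r1.letters == r2.letters

    def test_single_group(self):
        assert tukey_groups({"only": np.array([1.0, 2.0])}).letters == {"only": "a"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pair_significance_matches_statsmodels(self, seed):
        """The not-different pair set agrees with pairwise_tukeyhsd."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 6))
        groups = {f"g{i}": rng.normal(rng.uniform(0, 4), 1.0, 5) for i in range(k)}
        res = tukey_groups(groups, log_transform=False)
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = pairwise_tukeyhsd(data, labels, alpha=0.05)
        sm_nd = {
            tuple(sorted((a, b)))
            for (a, b), rej in zip(
                [(r[0], r[1]) for r in sm.summary().data[1:]], sm.reject
            )
            if not rej
        }
        ours = {tuple(sorted(p)) for p in res.not_different}
        assert ours == sm_nd
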
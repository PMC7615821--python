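# semfluency

Semantic-coherence analysis of category verbal fluency: score answer
sequences in a word-vector (LSA) semantic space, relate the scores to
self-rated language interest at the cohort level, and map their structural
correlates with a voxelwise gray-matter GLM under permutation family-wise
error control.

## Who this is for

Researchers in computational psychiatry and neurolinguistics who have
verbal-fluency transcripts (e.g. 60-second animal naming), want objective
coherence statistics instead of — or alongside — plain correct-word counts,
and need the downstream cohort and voxel-based-morphometry statistics in
one reproducible pipeline. Because clinical study data of this kind usually
cannot be shared, the package also ships first-class synthetic generators
that emulate every input at study scale, so each stage is testable and
demonstrable without access to protected data.

## The statistics at the core

Given a semantic space that maps words `w` to vectors `v(w)`:

* **Mean adjacent cosine similarity (coherence).** After NA-coding a
  transcript (out-of-vocabulary answers, repetitions after the first
  naming, and disallowed answers such as category names or breeds become
  NA), average `cos(v(w_i), v(w_{i+1}))` over consecutive positions where
  both answers are valid. An NA between two valid words breaks the pair —
  the flanking words are never bridged. High values mean retrieval moved
  between semantically close animals; low values mean jumpier, more random
  retrieval.
* **Mean vector length.** Average `||v(w)||` over valid answers; longer
  vectors indicate more specific, less frequent words.
* **n_correct.** The count of valid answers.

Cohort stage: OLS of each statistic on the SAMQ language item (self-rated
interest in language, Likert −3..+3), `n_correct`, age and gender. VBM
stage: voxelwise OLS of gray-matter intensity on the coherence score with
SAMQ, `n_correct`, age, gender and total intracranial volume as covariates;
voxel-level FWE by Freedman–Lane max-T permutation,
`p_fwe(v) = (1 + #{perm: max|T| ≥ |t(v)|}) / (1 + n_perm)`.

See `docs/methods.md` for conventions, generator design and limitations.

## Worked example

Score one transcript on a tiny hand-made space:

```python
import numpy as np
from semfluency import SemanticSpace, Transcript, score_transcript

space = SemanticSpace(
    ("hund", "katze", "maus", "esel"),
    np.array([[3.0, 4.0], [0.0, 2.0], [4.0, 3.0], [1.0, 0.0]]),
)
t = Transcript("p01", ("Hund", "Katze", "xqzz", "Maus", "hund"))
print(score_transcript(t, space))
```

```
FluencyScores(participant_id='p01', n_correct=3, mean_vector_length=4.0,
              mean_cosine_similarity=0.8, n_valid_pairs=1,
              n_oov=1, n_duplicate=1, n_disallowed=0)
```

`xqzz` is out of vocabulary and the second `hund` is a repetition, so three
answers count as correct; the only fully valid adjacent pair is
(hund, katze) with cosine 8/(5·2) = 0.8, and the mean vector length is
(5 + 2 + 5)/3 = 4.0.

Simulate a study-scale cohort (n = 101, planted SAMQ effect on coherence)
and fit the cohort regression:

```python
from semfluency.synthetic import CohortSpec, simulate_cohort
from semfluency.cohort_stats import fit_model

table, _ = simulate_cohort(CohortSpec(seed=7))
res = fit_model(table, "mean_cosine_similarity",
                ["samq", "n_correct", "age", "gender"])
print(res.to_frame().round(4).to_string(index=False))
```

```
     term    beta     se       t      p
intercept  0.3829 0.0186 20.5368 0.0000
     samq  0.0046 0.0016  2.8788 0.0049
n_correct -0.0004 0.0004 -0.8394 0.4033
      age -0.0012 0.0005 -2.3396 0.0214
   gender -0.0056 0.0055 -1.0197 0.3104
```

The generator planted a SAMQ coefficient of 0.004 on the coherence score;
this replicate recovers 0.0046 with a clearly positive t-ratio, while the
item count carries no effect, as planted.

## Command line

A `semfluency` console script wraps the library:

```bash
semfluency --seed 3 --out-dir out simulate --n 101      # synthetic cohort
semfluency --config run.yaml score                      # transcripts -> scores.csv
semfluency --config run.yaml cohort                     # the two regressions
semfluency --config run.yaml vbm                        # t-map, p_fwe-map, clusters
semfluency --config run.yaml calibrate                  # lambda -> target coherence
semfluency --seed 1 fwer-null --n-datasets 100          # null FWER check
semfluency build-space corpus.txt space.txt -k 50
semfluency load-space-info space.txt
```

Every output file gets a `.meta.json` sidecar with the config hash and the
seed that produced it.

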
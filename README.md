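# psekit

Binary sequence classification for DNA, RNA and protein/peptide data from
pseudo-component features and an RBF-kernel support vector machine.

Many questions in genome and proteome analysis reduce to a two-class
problem over sequences: is this genomic window a nucleosome-positioning
region, is this site a recombination spot, does this peptide carry a
modification?  `psekit` automates the construction of such predictors: you
supply a benchmark of positive and negative FASTA sequences, and the
package extracts features, jointly tunes the feature and classifier
hyperparameters by cross-validation, trains the final model, and applies it
to query sequences.

## The feature model

Sequences of different lengths are mapped to fixed-dimension vectors that
keep both composition and sequence-order information:

* **PseKNC** (pseudo k-tuple nucleotide composition) for DNA/RNA: a 4^k
  k-mer frequency block plus λ pseudo components from physicochemical
  correlations between dinucleotides at increasing lags, using six
  standardized helical parameters (Twist, Tilt, Roll, Shift, Slide, Rise).
* **PseAAC** (pseudo amino acid composition) for protein: the 20-dim amino
  acid composition (k = 1) plus λ correlation components from
  hydrophobicity, hydrophilicity and side-chain mass.

With f the composition block (Σf = 1), the tier-j *parallel* (type-I)
correlation factor is

    θ_j = mean_i Θ(u_i, u_{i+j}),    Θ(a,b) = (1/Λ) Σ_ξ [P_ξ(a) − P_ξ(b)]²

over units u (dinucleotides for DNA/RNA, residues for protein) whose
property values P_ξ are standardized to mean 0 / SD 1 over the alphabet; a
*series* (type-II) mode with per-property products is also available.  The
feature vector is

    x_u = f_u / (1 + wT)  (u ≤ 4^k),   x_{4^k+j} = w θ_j / (1 + wT),

with w the pseudo-block weight and T the sum of all correlation factors,
so every vector sums to one.  An RBF-SVM, K(x,y) = exp(−γ‖x−y‖²), is
trained on these vectors; the joint grid over (k, λ, w, C, γ) is scored by
pooled K-fold (or jackknife) cross-validation on one shared fold
assignment, and the winner — ties going to the simpler model — is refit on
the full benchmark.  Reported metrics are Acc, MCC, Sn, Sp and AUC.

## Worked example

Build a synthetic benchmark whose 30 positives each carry the 8-bp motif
`ACGTACGT` inside 60 bp of random background, then train over an
8-candidate grid:

```sh
python - <<'EOF'
from psekit.synthetic_data import SyntheticSpec, write_benchmark
write_benchmark(SyntheticSpec(seed=13, n_per_class=30, length=60,
                              motif="ACGTACGT", insertion_prob=1.0), "demo")
EOF
psekit train --molecule DNA --pos demo/pos.fasta --neg demo/neg.fasta \
  --out-dir demo/run --cv 5 --seed 13 \
  --grid-k 4,5 --grid-lambda 1,2 --grid-w 0.1 --grid-c 1,16 --grid-gamma 64
```

The log reports the selected candidate and its pooled 5-fold CV objective:

```
INFO best candidate: Candidate(k=4, lam=1, w=0.1, mode='parallel', C=1.0, gamma=64.0) (acc=0.9667)
```

and `demo/run/` receives the model archive (`model.pse`), the per-candidate
grid report, the CV metric table, ROC points and a ROC PNG.
`cv_metrics.tsv` holds the winner's pooled cross-validated scores — here
Acc 0.967, MCC 0.935, Sn 1.0, Sp 0.933, AUC 0.973 — meaning 58 of the 60
held-out predictions were correct and every positive was recovered.
Scoring query sequences:

```sh
psekit predict --model demo/run/model.pse --query demo/pos.fasta --out-dir demo/pred
```

writes one row per query with its signed SVM decision value and ±1 label:

```
id      decision_score          predicted_label
pos_0000  0.9999122008466599    1
pos_0001  1.0000015905930002    1
```

A positive score predicts the positive class.  The same pipeline is
available as a library (`psekit.load_benchmark`, `psekit.build_grid`,
`psekit.search`, `psekit.fit_final_model`, ...), and `--cv jackknife`
switches the selection to leave-one-out.

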
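# structalert

Structural-alert mining, SMARTS screening, and applicability-domain
gating for chemical toxicity endpoints.

A *structural alert* (SA) is a substructure whose presence in a molecule
signals potential for a specific toxicity — the working currency of
expert systems for mutagenicity, hepatotoxicity, skin sensitization and
similar endpoints.  `structalert` mines such alerts from labeled
compound collections by frequency analysis, stores them as SMARTS,
screens query structures against them with matched-atom reporting, and
evaluates alert sets with the standard classification statistics.  It
is aimed at computational toxicologists and cheminformaticians who want
a transparent, scriptable alternative to hosted alert servers.

## The method

Given a cleaned endpoint dataset (unique canonical SMILES, binary
labels), the *positive rate* of a substructure is

    PR = N_fragment_positive / N_fragment

where `N_fragment` counts the compounds containing it and
`N_fragment_positive` the toxic ones among them.  Two mining branches
are provided:

- **Fingerprints filter** — scan a predefined substructure-key catalog
  (the role the 4,860-key Klekota–Roth fingerprint plays at database
  scale; a curated ~30-key toxicophore catalog is bundled, and any
  SMARTS-per-line file plugs in).  A key becomes an alert iff it occurs
  in ≥ 6 compounds, has Fisher feature score ≥ 0.005, and PR ≥ 0.65
  (all inclusive).
- **SARpy-style enumeration** — cleave every training compound at all
  acyclic single bonds, enumerate every fragment of 2–18 heavy atoms,
  keep fragments found in ≥ 3 compounds with PR ≥ 0.65, and prune a
  fragment when a kept, more general sub-fragment is at least as
  predictive.

Prediction is the expert-system rule: a query containing **one or more
alerts** is predicted positive for the endpoint.  Reliability is flagged
by a Tanimoto applicability domain on the catalog fingerprints,

    Tc = N_ab / (N_a + N_b − N_ab)

with a query in-domain when `Tc ≥ 0.5` against at least one training
compound.  Alert sets are scored by total accuracy (Q), sensitivity
(SE), specificity (SP), and positive predictive value (PPV).

## Worked example

Mine alerts from a seeded synthetic dataset with one planted nitro
alert, then screen two queries:

```python
from structalert import (FixtureSpec, PlantedAlert, generate_dataset,
                         StructuralAlertClassifier, SubstructureCatalog)
from structalert.evaluation import format_report

spec = FixtureSpec(seed=7, n_compounds=40,
                   planted_alerts=[PlantedAlert("[N+](=O)[O-]", 0.25, 0.9)],
                   decoys=["C(=O)O"], endpoint="mutagenicity-demo")
dataset, manifest = generate_dataset(spec)

clf = StructuralAlertClassifier(
    catalog=SubstructureCatalog.from_smarts(["[N+](=O)[O-]", "C(=O)O"], name="demo"),
    endpoint="mutagenicity-demo",
).fit(dataset.smiles(), dataset.labels())

for alert in clf.alerts_:
    s = alert.stats
    print(f"{alert.alert_id}  {alert.smarts}  support={s.n_fragment} "
          f"PR={s.pr:.2f} f={s.f_score:.3f}")
print(format_report([clf.evaluate()]))
print(clf.screen(["O=[N+]([O-])c1ccccc1", "CCO"]).to_string(index=False))
```

prints

```
mutagenicity-demo_fp_filter_0000  [N+](=O)[O-]  support=10 PR=0.90 f=0.229
         endpoint stratum  n  n_alerts  TP  FP  TN  FN   SE%   SP%    Q%  PPV%
mutagenicity-demo     all 40         1   9   1  18  12 42.86 94.74 67.50 90.00
query_id               smiles  verdict                        alert_ids  in_domain  max_similarity nearest_training_id
      q0 O=[N+]([O-])c1ccccc1 positive mutagenicity-demo_fp_filter_0000       True             1.0               c0003
      q1                  CCO negative                                       False             0.0               c0000
```

The nitro key was planted in 10 of 40 compounds, 9 of them toxic, and
is recovered with exactly those counts (support 10, PR 0.90); the decoy
carboxylic-acid key, embedded at the background label rate, is
rejected.  Nitrobenzene fires the alert and is inside the domain;
ethanol carries no alert and no catalog key, so it is flagged
out-of-domain.  The resubstitution table shows the one-alert set is
conservative: high SP and PPV, modest SE.

The same workflow is available from the shell:

```bash
structalert fixture --spec spec.yaml --out fix/
structalert mine --in fix/dataset.csv --method both --out alerts.json --domain-out domain.json
structalert screen --alerts alerts.json --domain domain.json --in queries.smi --out report.csv
structalert evaluate --in fix/dataset.csv --alerts alerts.json --domain domain.json --ad-stratify
```

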
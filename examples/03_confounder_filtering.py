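"""Defeating a known confounder with an external filtering set.

The development cohort is constructed so that a hidden binary confounder
(think tumor histology) is associated with the survival endpoint during
development but not in the validation population. A block of features
tracks the confounder, another the true endpoint, a third both. Nine
unlabeled samples drawn from a single confounder stratum — samples that
could never be used for training — serve as an external filtering set:
atomic classifiers must not classify them all as the negative class.

Sweeping the lower bound on the externally-classified positive fraction
(0, 0.3, 0.6; upper bound fixed at 1.0) progressively removes atomic
classifiers that lean on the confounder. Development-set AUC falls while
validation AUC rises and the optimism gap closes.
"""

import drcomb as dc
from drcomb.filtering import ExternalFilter

spec = dc.FixtureSpec(
    n_per_class_dev=30, n_per_class_val=60, n_informative=60,
    n_noise=300, effect_size=1.0, rng_seed=31,
    confounder=dc.ConfounderSpec(
        dev_association=0.7, confounder_effect=1.6,
        n_confounded=120, n_mixed=120, n_ambiguous_external=9,
    ),
)
dev, val, external = dc.make_confounded_pair(spec)

print("external-proportion   dev OOB   validation   gap")
for lower in (0.0, 0.3, 0.6):
    config = dc.DRCConfig(
        n_realizations=40, k=9, max_order=1, dropout_d=10,
        dropout_iterations=1000, rng_seed=2,
        external=ExternalFilter(
            external, class_of_interest=1,
            proportion_lower=lower, proportion_upper=1.0,
        ),
    )
    master = dc.train_master(dev, config)
    oob = dc.roc_auc(master.score(dev, mode="oob"), dev.labels).auc
    va = dc.roc_auc(master.score(val), val.labels).auc
    print(f"  lower >= {lower:<10.1f} {oob:7.3f} {va:10.3f} {oob - va:+8.3f}")

print(
    "\nTightening the external constraint rejects confounder-driven\n"
    "atomic classifiers (they classify the single-stratum external set\n"
    "uniformly), trading inflated development AUC for real validation\n"
    "performance."
)
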
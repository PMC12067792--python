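"""Attribute-hierarchy validation on the ECPE grammar section.

The ECPE data (2,922 examinees x 28 items, three attributes) ship with the
CDM R package and are not redistributed here.  Export them to CSV first::

    Rscript -e 'library(CDM); data(data.ecpe);
                write.csv(data.ecpe$data[,-1], "data/ecpe_responses.csv",
                          row.names=FALSE)'

The much-studied linear hierarchy says lexical rules (attribute 3) are
prerequisite to cohesive rules (2), which are prerequisite to
morphosyntactic rules (1); the Wald tests check structural parameters
pi_2, pi_3, pi_5, pi_6 of the saturated model.
"""

from pathlib import Path

import cdmhier as ch
from cdmhier.datasets import ecpe_linear_hierarchy, ecpe_qmatrix, load_ecpe
from cdmhier.em import fit_nested
from cdmhier.information import (
    covariance, obs_information, score_contributions, xpd_information,
)

path = Path("data/ecpe_responses.csv")
hierarchy = ecpe_linear_hierarchy()
print("Q-matrix: 28 items x 3 attributes;",
      "items per attribute:", ecpe_qmatrix().sum(axis=0))
print("hierarchy:", sorted(hierarchy.prerequisites),
      "-> permissible patterns", ch.permissible_set(hierarchy))

if not path.exists():
    raise SystemExit(f"{path} not found - export the data as shown above.")

X, Q = load_ecpe(path)
sat, restricted = fit_nested(X, Q, hierarchy)
cov_xpd = covariance(xpd_information(score_contributions(sat, X)), "XPD", sat)
cov_obs = covariance(obs_information(sat, X), "Obs", sat)
for res in (ch.wald_test(sat, cov_xpd, hierarchy),
            ch.wald_test(sat, cov_obs, hierarchy),
            ch.lr_test(sat, restricted)):
    print(res)
# p-values near 0.02 reject the linear hierarchy at alpha = 0.05 but retain
# it at alpha = 0.01 - the ambiguity the method is designed to quantify.
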
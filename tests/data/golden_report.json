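{
  "alpha": 0.05,
  "level": 0.95,
  "methods": {
    "H": {
      "auc": 1.0,
      "auc_ci": null,
      "bs": 0.3803355135565049,
      "bs_norm": -1.3770969597281548,
      "calibration_p": {
        "crps_regression": 0.9324676771538266,
        "crps_unconditional": 0.7823344070933986,
        "ls_regression": 0.9190574483352013,
        "ls_unconditional": 0.7473318239198219
      },
      "chisq_p": 0.013073371645629647,
      "expected_significant": 3.5288404545973355,
      "harmonic_p": 0.8373782261608939,
      "ks_p": 0.08659424934816273,
      "label": "H",
      "mean_crps": 0.11803266425694314,
      "mean_ls": -0.1737002404835961,
      "mean_qs": -1.1855243322830364,
      "n": 5,
      "observed_significant": 1,
      "pi_coverage": 1.0,
      "pit_values": [
        0.14045465788019262,
        0.27887254441621384,
        0.15380981544179784,
        0.12248782548455267,
        0.6129201509968022
      ],
      "significance_probs": [
        0.8254491763107036,
        0.8770605069954148,
        0.7043540499313952,
        0.7605711716617882,
        0.3614055496980333
      ],
      "slope": null,
      "slope_ci": null,
      "slope_status": "not_estimable",
      "spiegelhalter_p": 0.02987440280346696,
      "spiegelhalter_z": 2.17175161801281
    },
    "N": {
      "auc": 1.0,
      "auc_ci": null,
      "bs": 0.41784110195266067,
      "bs_norm": -1.6115068872041283,
      "calibration_p": {
        "crps_regression": 0.6163129556362468,
        "crps_unconditional": 0.8228884265378392,
        "ls_regression": 0.7221142253401158,
        "ls_unconditional": 0.7768867716750839
      },
      "chisq_p": 0.00727061498473688,
      "expected_significant": 3.6590196637741945,
      "harmonic_p": 0.7259797973624785,
      "ks_p": 0.07109118912202485,
      "label": "N",
      "mean_crps": 0.12008326473895894,
      "mean_ls": -0.15161396953608672,
      "mean_qs": -0.8996769881929202,
      "n": 5,
      "observed_significant": 1,
      "pi_coverage": 1.0,
      "pit_values": [
        0.11372517569816604,
        0.2633593713856278,
        0.07440171225609207,
        0.08736858316478907,
        0.6312683478525598
      ],
      "significance_probs": [
        0.8526964327159081,
        0.894918677110857,
        0.7763374952072791,
        0.7957699184423659,
        0.3392971402977841
      ],
      "slope": null,
      "slope_ci": null,
      "slope_status": "not_estimable",
      "spiegelhalter_p": 0.009415399374901948,
      "spiegelhalter_z": 2.5965908834395766
    },
    "PM": {
      "auc": 1.0,
      "auc_ci": null,
      "bs": 0.263,
      "bs_norm": -0.6437499999999995,
      "calibration_p": {},
      "chisq_p": 0.06788915486182878,
      "expected_significant": 3.0,
      "harmonic_p": null,
      "ks_p": null,
      "label": "PM",
      "mean_crps": null,
      "mean_ls": null,
      "mean_qs": null,
      "n": 5,
      "observed_significant": 1,
      "pi_coverage": null,
      "pit_values": [],
      "significance_probs": [
        0.6,
        0.8,
        0.35,
        0.55,
        0.7
      ],
      "slope": null,
      "slope_ci": null,
      "slope_status": "not_estimable",
      "spiegelhalter_p": 0.5132306597464762,
      "spiegelhalter_z": 0.6538155301572051
    },
    "S": {
      "auc": 1.0,
      "auc_ci": null,
      "bs": 0.3153493394815166,
      "bs_norm": -0.9709333717594781,
      "calibration_p": {
        "crps_regression": 0.820088053723814,
        "crps_unconditional": 0.8571937642855615,
        "ls_regression": 0.8505403735330467,
        "ls_unconditional": 0.8936774156312606
      },
      "chisq_p": 0.04754950636687168,
      "expected_significant": 3.141152251512445,
      "harmonic_p": 0.8545778226760686,
      "ks_p": 0.1553979902890137,
      "label": "S",
      "mean_crps": 0.09841651566955337,
      "mean_ls": -0.35509821805591096,
      "mean_qs": -1.2171310042389283,
      "n": 5,
      "observed_significant": 1,
      "pi_coverage": 1.0,
      "pit_values": [
        0.17388975430720244,
        0.328851598421519,
        0.12206738947435353,
        0.1406908864900135,
        0.8392116349398262
      ],
      "significance_probs": [
        0.7797727737207634,
        0.8589934952890717,
        0.6675727815539053,
        0.695532763833616,
        0.1392804371150887
      ],
      "slope": null,
      "slope_ci": null,
      "slope_status": "not_estimable",
      "spiegelhalter_p": 0.132676421269805,
      "spiegelhalter_z": 1.5036309350761878
    },
    "SH": {
      "auc": 1.0,
      "auc_ci": null,
      "bs": 0.25817816827509493,
      "bs_norm": -0.6136135517193427,
      "calibration_p": {
        "crps_regression": 0.8398257225486414,
        "crps_unconditional": 0.5451490558008221,
        "ls_regression": 0.8149438858229221,
        "ls_unconditional": 0.5568180112514711
      },
      "chisq_p": 0.09056573745125525,
      "expected_significant": 2.8712090512821455,
      "harmonic_p": 0.661366782354049,
      "ks_p": 0.196813594676711,
      "label": "SH",
      "mean_crps": 0.09504088016529946,
      "mean_ls": -0.3557396231745741,
      "mean_qs": -1.5167664914252434,
      "n": 5,
      "observed_significant": 1,
      "pi_coverage": 1.0,
      "pit_values": [
        0.21508587557702558,
        0.3514285964409646,
        0.2587310145900896,
        0.1981371703172033,
        0.8668298683157118
      ],
      "significance_probs": [
        0.7383445251610161,
        0.8337885514976325,
        0.5436119470512677,
        0.6396814940988991,
        0.1157825334733304
      ],
      "slope": null,
      "slope_ci": null,
      "slope_status": "not_estimable",
      "spiegelhalter_p": 0.3805747373440934,
      "spiegelhalter_z": 0.87683781316181
    }
  },
  "n_oriented": 1,
  "n_pairs": 5,
  "report_version": 1
}
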
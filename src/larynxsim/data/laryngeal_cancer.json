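{
 "initial_state": "Initial",
 "name": "laryngeal_cancer",
 "states": {
  "CancerDeath": {
   "kind": "Death",
   "payload": {
    "week_attribute": "cancer_death_week"
   },
   "provenance": "death within the 5-year survival window (all-cause anchors)",
   "transitions": []
  },
  "CareTimeline": {
   "kind": "Simple",
   "payload": {
    "action": "build_timeline"
   },
   "provenance": "four key encounters; symptom onset up to one year before diagnosis",
   "transitions": [
    {
     "to": "SurvivalSubmodule"
    }
   ]
  },
  "Diagnosis": {
   "kind": "ConditionOnset",
   "payload": {
    "code": "ICD-10:C32",
    "label": "Laryngeal cancer"
   },
   "provenance": "diagnosis confirmed at the second doctor visit",
   "transitions": [
    {
     "to": "TreatmentAssignment"
    }
   ]
  },
  "Initial": {
   "kind": "Initial",
   "payload": {},
   "provenance": "module entry",
   "transitions": [
    {
     "to": "OnsetGate"
    }
   ]
  },
  "NoDisease": {
   "kind": "Terminal",
   "payload": {},
   "provenance": "person never develops laryngeal cancer",
   "transitions": []
  },
  "OnsetGate": {
   "kind": "Delay",
   "payload": {
    "hazard_table": "incidence",
    "on_expire": "NoDisease",
    "on_fire": "RiskProfile"
   },
   "provenance": "Cancer Registry Schleswig-Holstein, laryngeal cancer 1997-2021: gender- and age-specific probability of disease, age <40 excluded",
   "transitions": []
  },
  "RiskProfile": {
   "kind": "Simple",
   "payload": {
    "action": "risk_profile"
   },
   "provenance": "risk factor frequencies: placeholder estimates (smoking/alcohol literature)",
   "transitions": [
    {
     "to": "TumorCharacterization"
    }
   ]
  },
  "SurvivalSubmodule": {
   "kind": "Simple",
   "payload": {
    "action": "survival_submodule"
   },
   "provenance": "Cancer Registry Schleswig-Holstein, laryngeal cancer 1997-2021: 5-year overall survival by stage and age group (100 yearly nodes)",
   "transitions": [
    {
     "condition": {
      "attr": "cancer_died",
      "op": "eq",
      "value": true
     },
     "to": "CancerDeath"
    },
    {
     "to": "Survivorship"
    }
   ]
  },
  "Survivorship": {
   "kind": "Terminal",
   "payload": {},
   "provenance": "alive at 5 years; reverts to background mortality",
   "transitions": []
  },
  "TreatmentAssignment": {
   "kind": "Simple",
   "payload": {
    "action": "assign_treatment"
   },
   "provenance": "German S3 guideline for laryngeal cancer; second-line options carried at the 10% evidence-gap frequency",
   "transitions": [
    {
     "to": "CareTimeline"
    }
   ]
  },
  "TumorCharacterization": {
   "kind": "Simple",
   "payload": {
    "action": "characterize_tumor"
   },
   "provenance": "Cancer Registry Schleswig-Holstein, laryngeal cancer 1997-2021: T by sex, N by T and sex, M by T and N; UICC compiled from TNM",
   "transitions": [
    {
     "to": "Diagnosis"
    }
   ]
  }
 }
}
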
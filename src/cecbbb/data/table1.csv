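# Experimental reference dataset: 57 ionized drugs profiled by open-tubular CEC
# (retention factor k') and automated pH-metric titration (pKa, log P, log D7.4),
# with literature in vivo log BB values.
# k_prime_sd, pka_sd, logp_sd: standard deviations over three independent experiments.
# charge_kind and protolyte_kind are curator-provided annotations assigned from
# standard drug ionization chemistry (carboxylic acids, barbiturates and the
# thymine N-H of zidovudine as acids; amines as bases); they are not part of the
# measured data. levofloxacin is an ampholyte with a second pKa of 6.04; the
# value 8.13 in the pka column is the one used for regression.
compound_id,k_prime,k_prime_sd,pka,pka_sd,logp,logp_sd,logd74,logbb,charge_kind,protolyte_kind,pka2
acetylsalicylic acid,0.03441,0.00987,3.36,0.00,1.31,0.01,-2.73,-1.30,acid,monoprotic_acid,
amitriptyline,0.00004,0.00001,9.23,0.08,4.68,0.02,2.84,1.30,base,monoprotic_base,
atenolol,0.00183,0.00051,9.50,0.01,0.06,0.01,-2.04,-1.00,base,monoprotic_base,
atropine,0.00440,0.00309,9.84,0.03,1.73,0.01,-0.72,-0.06,base,monoprotic_base,
betahistine,0.03582,0.00587,9.84,0.00,0.49,0.01,-1.95,-0.30,base,monoprotic_base,
bromperidol,-0.00795,0.00034,8.45,0.10,3.87,0.05,2.81,1.38,base,monoprotic_base,
buspirone,0.02096,0.00194,7.62,0.00,2.89,0.02,2.47,0.48,base,monoprotic_base,
chlorambucil,0.00397,0.00087,4.72,0.04,3.71,0.02,1.07,-1.70,acid,monoprotic_acid,
chlorpromazine,0.34688,0.03015,9.07,0.01,5.10,0.03,3.43,1.06,base,monoprotic_base,
citalopram,0.00405,0.00229,9.43,0.05,3.42,0.00,1.39,0.48,base,monoprotic_base,
cyclobarbital,0.00186,0.00088,7.71,0.02,1.33,0.01,1.16,-0.30,acid,monoprotic_acid,
desipramine,-0.01523,0.00343,10.25,0.02,4.00,0.01,1.35,1.20,base,monoprotic_base,
diclofenac,0.00802,0.00320,4.19,0.01,4.33,0.01,1.26,-1.70,acid,monoprotic_acid,
donepezil,-0.01233,0.00010,9.10,0.02,3.90,0.02,2.19,0.89,base,monoprotic_base,
fluphenazine,0.11096,0.00192,7.79,0.07,5.12,0.06,4.58,1.51,base,monoprotic_base,
galanthamine,0.00203,0.00150,8.32,0.00,1.15,0.00,0.18,0.00,base,monoprotic_base,
haloperidol,-0.00906,0.00138,8.66,0.08,4.37,0.08,3.18,1.34,base,monoprotic_base,
hydroxyzine,-0.00058,0.00031,7.66,0.04,3.73,0.03,3.34,0.90,base,monoprotic_base,
ibuprofen,-0.03690,0.00011,4.62,0.05,3.80,0.00,1.07,-0.18,acid,monoprotic_acid,
imipramine,-0.04094,0.00432,9.45,0.12,4.44,0.01,2.39,1.30,base,monoprotic_base,
indomethacin,0.01869,0.00624,4.71,0.01,6.31,0.12,3.92,-1.26,acid,monoprotic_acid,
ketorolac,0.02127,0.00131,3.64,0.06,2.90,0.04,-0.05,-2.00,acid,monoprotic_acid,
clonidine,0.00321,0.00046,8.12,0.01,1.53,0.01,0.74,0.11,base,monoprotic_base,
clozapine,0.00693,0.00245,7.58,0.01,3.92,0.10,3.52,0.60,base,monoprotic_base,
codeine,-0.01188,0.00888,8.22,0.05,1.14,0.01,0.26,0.55,base,monoprotic_base,
levofloxacin,-0.04345,0.00321,8.13,0.00,0.82,0.01,0.77,-0.70,base,ampholyte,6.04
loperamide,0.01470,0.00102,8.69,0.12,4.69,0.17,3.21,0.70,base,monoprotic_base,
mepyramine,0.00817,0.00067,8.71,0.05,2.73,0.02,1.48,0.49,base,monoprotic_base,
metoclopramide,-0.00563,0.00136,9.32,0.02,2.31,0.01,0.38,0.08,base,monoprotic_base,
metoprolol,-0.00612,0.00036,9.50,0.13,1.57,0.01,-0.53,1.15,base,monoprotic_base,
mianserin,-0.02148,0.00155,7.25,0.03,3.74,0.01,3.50,0.99,base,monoprotic_base,
naproxen,0.01050,0.00460,4.47,0.09,3.11,0.00,0.27,-1.70,acid,monoprotic_acid,
nicotine,0.00897,0.00167,8.09,0.01,1.31,0.01,0.54,0.40,base,monoprotic_base,
nortriptyline,-0.01133,0.00210,10.05,0.03,4.29,0.01,1.79,1.04,base,monoprotic_base,
paroxetine,0.02144,0.00689,9.76,0.08,3.39,0.04,1.19,0.48,base,monoprotic_base,
phenobarbital,-0.01824,0.00855,7.43,0.06,1.26,0.01,0.98,-0.12,acid,monoprotic_acid,
phenylbutazone,0.00083,0.00015,4.58,0.05,3.64,0.01,0.96,-0.52,acid,monoprotic_acid,
physostigmine,0.01268,0.00087,8.24,0.04,1.69,0.03,0.81,0.08,base,monoprotic_base,
pindolol,0.00127,0.00052,9.62,0.07,1.91,0.01,-0.28,0.30,base,monoprotic_base,
promazine,-0.01399,0.00228,9.39,0.00,4.54,0.00,2.55,1.23,base,monoprotic_base,
propranolol,0.00202,0.00061,9.46,0.01,3.31,0.01,1.29,0.85,base,monoprotic_base,
quinidine,0.00340,0.00040,8.82,0.03,3.50,0.00,2.08,0.33,base,monoprotic_base,
ranitidine,-0.00256,0.00041,8.43,0.01,0.34,0.02,-0.75,-1.23,base,monoprotic_base,
risperidone,0.00698,0.00377,8.27,0.04,3.09,0.03,2.17,-0.02,base,monoprotic_base,
ropinirole,-0.01252,0.00126,9.70,0.05,3.24,0.01,0.94,0.25,base,monoprotic_base,
rivastigmine,-0.00018,0.00009,8.91,0.01,2.18,0.01,0.66,0.88,base,monoprotic_base,
salbutamol,-0.01030,0.00502,9.60,0.01,0.30,0.04,-1.90,-1.03,base,monoprotic_base,
salicylic acid,0.02255,0.00676,2.79,0.01,2.31,0.01,-0.98,-1.10,acid,monoprotic_acid,
thioperamide,0.01849,0.00363,6.90,0.04,2.39,0.02,2.27,-0.16,base,monoprotic_base,
thioridazine,0.00911,0.00062,9.25,0.01,5.38,0.03,3.54,0.24,base,monoprotic_base,
trazodone,-0.01080,0.00292,6.83,0.04,2.98,0.00,2.88,0.30,base,monoprotic_base,
trifluoperazine,0.20277,0.00151,7.88,0.04,6.14,0.01,5.53,1.44,base,monoprotic_base,
triprolidine,0.01006,0.00233,9.39,0.06,3.87,0.01,1.88,0.78,base,monoprotic_base,
venlafaxine,-0.01411,0.00205,9.67,0.02,2.97,0.00,0.70,0.48,base,monoprotic_base,
verapamil,0.00675,0.00054,8.84,0.06,3.89,0.01,2.44,-0.52,base,monoprotic_base,
zidovudine,0.00428,0.00056,9.51,0.00,0.09,0.01,0.09,-1.00,acid,monoprotic_acid,
zolmitriptan,-0.00882,0.00356,9.60,0.05,1.19,0.01,-1.01,-1.40,base,monoprotic_base,
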
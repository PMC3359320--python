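country,policy,vg_pct,cc_pct,quality_pct,ranking
Malawi,National HIV Policy,66.7,81.0,42.8,Moderate
Malawi,National Medicine Policy,8.3,66.7,57.1,Moderate
Malawi,National Policy On Equalisation Of Opportunities For Persons With Disabilities,16.7,57.1,42.8,Low
Malawi,National Mental Health Policy,33.3,66.7,47.6,Low
Malawi,Malawi Policy On Tuberculosis Control In Prisons,25,52.4,38,Low
Malawi,Traditional Medicine Policy,8.3,61.9,42.8,Low
Malawi,Injection Safety Policy,16.7,61.9,42.8,Low
Malawi,National Health Policy,8.3,71.4,19.0,Low
Malawi,Policy On Equity In Access To Antiretroviral Therapy (Art) In Malawi,16.7,42.9,9.5,Low
Malawi,National Sexual And Reproductive Health And Rights (SRHR) Policy,25,71.4,23.8,Low
Malawi,Malaria Policy,25,52.4,38,Low
Malawi,National Policy On Orphans And Other Vulnerable Children,8.3,61.9,33.3,Low
Malawi,IMCI Approach Policy For Accelerated Child Survival And Development In Malawi,8.3,52.4,23.8,Low
Malawi,Infection Prevention And Control Policy,0,47.6,14.3,Low
Namibia,National Reproductive and child health policy,83,90,62,High
Namibia,National Gender Policy,75,71,52,High
Namibia,National Policy for Mental health,58,71,57,High
Namibia,National Policy on Disability,58,95,57,High
Namibia,National guidelines for the management of Tuberculosis,33,80,76,Moderate
Namibia,National Policy on HIV/AIDS,75,100,43,Moderate
Namibia,Policy on Orthopaedic Technical Services,50,66,48,Moderate
Namibia,National Malaria Policy,25,43,28,Low
Namibia,Control of Acute Respiratory Infections (ARI) Programme,25,43,10,Low
Namibia,Integrated Management of Childhood Illness (Diarrhoea),25,24,24,Low
South Africa,The HIV and AIDS and STI Strategic Plan for SA 2007-2011,66.6,80.95,66.66,High
South Africa,The White Paper for the Transformation of the Health System,50,52.38,42.86,Moderate
South Africa,Tuberculosis Strategic Plan for SA 2007-2011,50,62,47.62,Moderate
South Africa,Strategic Plan 2009/10-2011/12,41.6,57.14,38.09,Low
South Africa,Strategic Priorities for the National Health System 2004-2009,41.6,42.86,9.52,Low
South Africa,Policy on Quality in Health Care for SA,33.3,14.29,0,Low
South Africa,The National Rehabilitation Policy,41.6,47.62,19.04,Low
South Africa,The National Programme for control and management of Diabetes Type 2 at primary level,25,38.09,4.76,Low
South Africa,The South African Hypertension Guideline 2006,33.3,19.05,4.76,Low
South Africa,The National Guide on Stroke and Transient Ischaemic Attack Management,25,14.29,9.52,Low
South Africa,The Guidelines for Cholera Control,25,23.81,4.76,Low
Sudan,National Health policy,83,67,52,High
Sudan,South Sudan Health policy,75,62,57,High
Sudan,Mental Health policy,92,86,48,Moderate
Sudan,Disaster policy,75,57,29,Moderate
Sudan,Health promotion strategy,75,52,24,Moderate
Sudan,Non-Communicable diseases,92,62,38,Moderate
Sudan,Nutrition policy,67,57,29,Moderate
Sudan,Reproduction health policy,50,71,29,Moderate
Sudan,Women empowerment policy,17,29,10,Low
Sudan,Voluntary sector policy,0,29,5,Low
Sudan,TB policy,42,57,29,Low
Sudan,Malaria policy,42,38,29,Low
Sudan,AIDS policy,25,71,33,Low
Sudan,Private sector policy,0,52,19,Low
Sudan,Drugs policy,17,38,38,Low
Sudan,Disability policy,42,62,24,Low
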
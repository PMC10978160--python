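drug_id,name,forms,liquid_conc_mg_ml,reconst_conc_mg_ml,strengths_mg,corrosive,stability,poorly_soluble,packaging,has_holder_casing,high_avg_conc,recommended_dosage
MITC,mitomycin C,powder,,0.5;1,10;40,false,immediate_use,false,glass,false,false,10-20 mg/m2
DC,dacarbazine,powder,,1.4;2.0;2.8;4.0,100;1000,false,unknown,false,glass,true,true,200-250 mg/m2
RTX,raltitrexed,powder,,0.04;0.08,2,false,limited,false,glass,false,false,3 mg/m2
FTM,fotemustine,powder,,52,208,false,immediate_use,false,glass,true,false,100 mg/m2
DNR,daunorubicin,powder,,2,20,false,extended,false,glass,true,false,0.5-3 mg/kg
VNB,vinblastine,powder,,1,10,false,extended,false,glass,true,false,3.7 mg/m2
MP,melphalan,powder,,5,2;200,false,immediate_use,false,glass,false,true,8-200 mg/m2
VNC,vincristine,liquid,1,,1;5,false,immediate_use,false,glass;PP,false,false,0.4-1.4 mg/m2
CP,cyclophosphamide,powder,,20,200;500;1000,false,unknown,true,type III glass,false,true,12-240 mg/m2
PMX,pemetrexed,powder;liquid,25,25,100;500;1000,false,extended,false,glass,true,true,500 mg/m2
TPT,topotecan,powder,,1,1;4,false,extended,false,glass,false,false,1.5 mg/m2
EPI,epirubicin,liquid,2,,5;200,false,extended,false,amber glass,false,false,60-135 mg/m2
DXR,doxorubicin,liquid,2,,10;200,false,immediate_use,false,glass,false,false,50-75 mg/m2
IRT,irinotecan,liquid,1.5;20,,20;1000,false,extended,false,PP;glass,true,true,180-350 mg/m2
PTX,paclitaxel,liquid,6,,30;600,true,extended,false,glass;glass+PP,true,true,100-260 mg/m2
BSF,busulfan,liquid,6,,60,true,limited,false,glass,true,false,0.8-3.2 mg/kg
CarboPt,carboplatin,liquid,10,,50;600,false,extended,false,amber glass;PP,false,false,400 mg/m2
CisPt,cisplatin,liquid,0.5;1,,10;100,false,extended,false,amber glass;PP,true,false,50-120 mg/m2
DTX,docetaxel,liquid,10;20,,20;160,false,extended,false,amber glass;glass,true,false,75 mg/m2
IDC,idarubicin,liquid,1,,5;10,false,extended,false,glass,false,false,12 mg/m2
MT,methotrexate,liquid,7.5;100,,2.5;500,false,immediate_use,false,glass,true,false,10-25 mg/m2
5-FU,fluorouracil,liquid,40;50,,50;5000,true,extended,true,glass;aluminium,true,true,200-600 mg/m2
CTB,cytarabine,liquid,20;100,,100;5000,false,extended,false,glass,true,false,100-200 mg/m2
ETP,etoposide,liquid,20;100,,50;1000,false,extended,false,amber glass,true,false,60-200 mg/m2
OxaliPt,oxaliplatin,liquid,5,,50;250,false,extended,false,glass,true,false,85 mg/m2
VNR,vinorelbine,liquid,10;20;80,,10;80,false,extended,false,glass;PVC,false,false,25-80 mg/m2
GEM,gemcitabine,powder;liquid,10,38,200;1000;2000,false,extended,false,glass,true,true,1000-1250 mg/m2
IP,ifosfamide,powder,,40,500;1000;2000,false,unknown,false,glass,false,true,1200-2400 mg/m2
VND,vindesine,powder,,1,1;5,false,unknown,false,glass,false,false,3 mg/m2
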
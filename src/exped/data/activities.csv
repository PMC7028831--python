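name,met,team,competition,pacing
soccer,7.0,team,competitive,external
field_hockey,8.0,team,competitive,external
basketball,8.0,team,competitive,external
volleyball,4.0,team,competitive,external
korfball,6.0,team,competitive,external
aerobics,6.5,team,non-competitive,external
spinning_class,8.5,team,non-competitive,external
rowing_crew,7.0,team,competitive,external
tennis,7.3,solitary,competitive,external
squash,12.0,solitary,competitive,external
badminton,5.5,solitary,competitive,external
judo,10.0,solitary,competitive,external
boxing,9.0,solitary,competitive,external
table_tennis,4.0,solitary,competitive,external
windsurfing,5.0,solitary,non-competitive,external
horse_riding,5.5,solitary,non-competitive,external
jogging,7.0,solitary,non-competitive,internal
swimming,6.0,solitary,non-competitive,internal
hiking,6.0,solitary,non-competitive,internal
fitness,4.5,solitary,non-competitive,internal
weight_training,3.5,solitary,non-competitive,internal
tour_cycling,4.0,solitary,non-competitive,internal
inline_skating,7.0,solitary,non-competitive,internal
nordic_walking,4.8,solitary,non-competitive,internal
yoga,2.5,solitary,non-competitive,internal
golf,4.3,solitary,competitive,internal
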